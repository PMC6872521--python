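"""Run the in silico candidate funnel on the KRAS G12V substrate.

Chains enumeration -> mutation filter -> length filter -> binding filter
with a constructed prediction table in which only the spliced candidate
KLVVGAVGV is a strong HLA-A*02:01 binder (50 nM) while the non-spliced
10mer KLVVVGAVGV is weak (300 nM > the 100 nM cutoff).  The funnel counts
shrink monotonically and the final candidate set contains exactly the
spliced epitope candidate.
"""

from pepsplice import kras_fixture, run_pipeline

fx = kras_fixture()
predictions = {
    fx.spliced_candidate: 50.0,  # strong binder
    fx.nonspliced_candidate: 300.0,  # weak binder, removed at the cutoff
}
result = run_pipeline(
    fx.g12v,
    mutation_position=12,
    mutant_residue="V",
    predictions=lambda s: predictions.get(s, 5000.0),
)

print("candidate funnel (sequence-level counts):")
print(result.funnel.to_string(index=False))
print("\nfinal candidates:")
for c in result.candidates:
    print(f"  {c.sequence}  category={c.category}  IC50={c.predicted_ic50:g} nM")
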