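"""Map the KRAS G12V spliced epitope candidate back onto its substrate.

The 9mer KLVVGAVGV can be explained by removing any one of the three
consecutive valines of the KRAS sequence, so it has three equivalent
cis-normal decompositions.  The script prints them, classifies the peptide,
and checks whether any protein of a small decoy proteome could also produce
it (by hydrolysis or cis splicing) -- the uniqueness property that makes it
a tumor-specific neoepitope candidate.
"""

import numpy as np

from pepsplice import (
    ProteinRecord,
    check_uniqueness,
    classify_peptide,
    kras_fixture,
    map_peptide,
)

fx = kras_fixture()
pep = fx.spliced_candidate
print(f"{pep} ({fx.spliced_candidate_name}) vs {fx.g12v.id}:")
decomps = map_peptide(pep, fx.g12v)
for d in decomps:
    print(
        f"  {d.category}: sr1={d.sr1[0]}-{d.sr1[1]}, sr2={d.sr2[0]}-{d.sr2[1]}, "
        f"intervening={d.intervening_length}, splice site after {d.psp_p1}"
    )
print(f"classification: {classify_peptide(decomps)} ({len(decomps)} equivalent explanations)")

# wild-type substrate cannot produce it at all
print(f"\nvs wild-type substrate: {classify_peptide(map_peptide(pep, fx.wild_type))}")

# uniqueness against a decoy proteome (plus the KRAS G12V source itself)
rng = np.random.default_rng(0)
aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
proteome = [ProteinRecord(id="KRAS_G12V", sequence=fx.g12v.sequence)] + [
    ProteinRecord(id=f"decoy{k}", sequence="".join(rng.choice(aas, size=200)))
    for k in range(20)
]
report = check_uniqueness(pep, proteome, source_ids=["KRAS_G12V"])
producers = report.table[report.table.any(axis=1)]
print(f"\nproteins able to produce {pep}:")
print(producers)
print(f"unique to the source antigen: {report.unique}")
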