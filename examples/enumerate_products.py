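"""Enumerate all theoretical proteasome products of the KRAS G12V substrate.

Counts the 8-12mer non-spliced, cis-normal and cis-reverse products of the
KRAS 2-35 G12V polypeptide at the coordinate level, collapses them to
unique sequences, and prints the first entries of the targeted-MS m/z
inclusion list built from them.
"""

from pepsplice import (
    build_inclusion_list,
    candidates_from_enumeration,
    enumerate_cis,
    enumerate_nonspliced,
    kras_fixture,
)

fx = kras_fixture()
sub = fx.g12v
print(f"substrate {sub.id}: {len(sub)} residues, positions {sub.first_position}-{sub.last_position}")

nonspliced = enumerate_nonspliced(sub, 8, 12)
cis_normal = enumerate_cis(sub, 8, 12, include_reverse=False)
cis_all = enumerate_cis(sub, 8, 12, include_reverse=True)
print(f"non-spliced coordinate entries : {len(nonspliced):>6}")
print(f"cis-normal coordinate entries  : {len(cis_normal):>6}")
print(f"cis incl. reverse              : {len(cis_all):>6}")

candidates = candidates_from_enumeration(nonspliced + cis_all)
print(f"unique peptide sequences       : {len(candidates):>6}")
spliced_only = [c for c in candidates if c.category != "non-spliced"]
print(f"  of which spliced-only        : {len(spliced_only):>6}")

peps = [c.sequence for c in candidates[:50]]
inclusion = build_inclusion_list(peps, charges=(2, 3))
print("\nfirst inclusion-list entries (monoisotopic m/z per charge state):")
print(inclusion.head(8).to_string(index=False))
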