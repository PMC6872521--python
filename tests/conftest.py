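import numpy as np
import pandas as pd
import pytest

from pepsplice import (
    Decomposition,
    QuantifiedProduct,
    Substrate,
    classify_peptide,
    kras_fixture,
    map_peptide,
)


@pytest.fixture(scope="session")
def kras():
    return kras_fixture()


def make_product(sequence, substrate, amount=1.0, times=(0.0, 1.0, 2.0), n_bio=2):
    """QuantifiedProduct with a flat amount, decompositions from mapping."""
    decomps = tuple(map_peptide(sequence, substrate))
    idx = pd.MultiIndex.from_product(
        [range(1, n_bio + 1), times], names=["bio_rep", "time_h"]
    )
    amounts = pd.Series(float(amount), index=idx)
    return QuantifiedProduct(
        sequence=sequence,
        decompositions=decomps,
        category=classify_peptide(decomps),
        amounts=amounts,
    )


def brute_force_decompositions(peptide, substrate, min_sr_len=1):
    """Independent oracle: quadruple loop over all one- and two-segment
    explanations of a peptide against a substrate."""
    seq = substrate.sequence
    off = substrate.numbering_offset
    L = len(seq)
    found = set()
    # one segment
    for i in range(L):
        j = i + len(peptide)
        if seq[i:j] == peptide:
            found.add(("non-spliced", (i + off, j - 1 + off), None))
    # two segments
    for i1 in range(L):
        for j1 in range(i1, L):
            left = seq[i1 : j1 + 1]
            if len(left) < min_sr_len or len(left) >= len(peptide):
                continue
            if not peptide.startswith(left):
                continue
            rest = peptide[len(left) :]
            if len(rest) < min_sr_len:
                continue
            for i2 in range(L):
                j2 = i2 + len(rest) - 1
                if j2 >= L or seq[i2 : j2 + 1] != rest:
                    continue
                a = (i1 + off, j1 + off)
                b = (i2 + off, j2 + off)
                if a[1] < b[0]:
                    cat = "cis-normal"
                elif b[1] < a[0]:
                    cat = "cis-reverse"
                else:
                    cat = "trans"
                found.add((cat, a, b))
    return found


def as_tuples(decomps):
    return {(d.category, d.sr1, d.sr2) for d in decomps}
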