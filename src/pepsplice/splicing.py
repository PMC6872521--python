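"""Enumeration and mapping of proteasome-generated peptide products.

The proteasome can release a contiguous substrate fragment (non-spliced
peptide) or ligate two fragments into a spliced peptide.  When both
splice-reactants come from the same substrate molecule the product is *cis*
spliced -- in normal order when the N-terminal reactant precedes the
C-terminal one in the substrate, in reverse order otherwise -- and *trans*
spliced when the two reactants can only be explained by two substrate
molecules (their coordinate intervals overlap).

A :class:`Decomposition` records one explanation of a product:
``sr1 = [i1, j1]`` is the N-terminal splice-reactant, ``sr2 = [i2, j2]`` the
C-terminal one (absent for non-spliced products).  All coordinates are
closed intervals in *parental* numbering: a substrate excised from a larger
protein (e.g. KRAS residues 2-35) carries a ``numbering_offset`` so that
position 12 means residue 12 of the parent.  The residue after which the
substrate was cleaved to form the product C-terminus (``scs_p1``) and the
C-terminus of the N-terminal splice-reactant (``psp_p1``) are derived from
the coordinates.

Splicing with exactly two reactants is modelled; peptides that would need
three or more fragments are reported as unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

NON_SPLICED = "non-spliced"
CIS_NORMAL = "cis-normal"
CIS_REVERSE = "cis-reverse"
TRANS = "trans"
UNMAPPED = "unmapped"

SPLICED_CATEGORIES = (CIS_NORMAL, CIS_REVERSE, TRANS)
#: Precedence for classifying a peptide from its decompositions.
CATEGORY_PRECEDENCE = (NON_SPLICED, CIS_NORMAL, CIS_REVERSE, TRANS)


@dataclass(frozen=True)
class Substrate:
    """A digestion substrate with parental residue numbering.

    ``numbering_offset`` is the parental position of the first residue;
    reported positions satisfy ``parental = internal_1based + offset - 1``.
    """

    id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("substrate sequence must have length >= 2")
        if self.numbering_offset < 1:
            raise ValueError("numbering offset must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def first_position(self) -> int:
        return self.numbering_offset

    @property
    def last_position(self) -> int:
        return self.numbering_offset + len(self.sequence) - 1

    def residue_at(self, parental_position: int) -> str:
        """Residue at a parental position."""
        i = parental_position - self.numbering_offset
        if not 0 <= i < len(self.sequence):
            raise IndexError(
                f"position {parental_position} outside substrate "
                f"[{self.first_position}, {self.last_position}]"
            )
        return self.sequence[i]

    def segment(self, start: int, end: int) -> str:
        """Sequence of the closed parental interval [start, end]."""
        if start > end:
            raise ValueError("interval start must be <= end")
        self.residue_at(start)
        self.residue_at(end)
        o = self.numbering_offset
        return self.sequence[start - o : end - o + 1]


@dataclass(frozen=True)
class Decomposition:
    """One explanation of a peptide as one or two substrate segments."""

    category: str
    sr1: tuple[int, int]
    sr2: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.category not in (NON_SPLICED,) + SPLICED_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        i1, j1 = self.sr1
        if i1 > j1:
            raise ValueError("sr1 interval reversed")
        if self.category == NON_SPLICED:
            if self.sr2 is not None:
                raise ValueError("non-spliced decomposition cannot carry sr2")
            return
        if self.sr2 is None:
            raise ValueError(f"{self.category} decomposition requires sr2")
        i2, j2 = self.sr2
        if i2 > j2:
            raise ValueError("sr2 interval reversed")
        disjoint_normal = j1 < i2
        disjoint_reverse = j2 < i1
        if self.category == CIS_NORMAL and not disjoint_normal:
            raise ValueError("cis-normal requires j1 < i2")
        if self.category == CIS_REVERSE and not disjoint_reverse:
            raise ValueError("cis-reverse requires j2 < i1")
        if self.category == TRANS and (disjoint_normal or disjoint_reverse):
            raise ValueError("trans requires overlapping segments")

    @property
    def intervening_length(self) -> int | None:
        """Residues strictly between the two splice-reactants.

        None for non-spliced products and for trans products (the two
        reactants come from different substrate molecules, so an intervening
        sequence is not defined)."""
        if self.category == CIS_NORMAL:
            return self.sr2[0] - self.sr1[1] - 1
        if self.category == CIS_REVERSE:
            return self.sr1[0] - self.sr2[1] - 1
        return None

    @property
    def psp_p1(self) -> int | None:
        """Parental position of the N-terminal splice-reactant's C-terminus
        (the splicing site P1); None for non-spliced products."""
        if self.category == NON_SPLICED:
            return None
        return self.sr1[1]

    @property
    def scs_p1(self) -> int:
        """Parental position of the product's C-terminal residue, i.e. the
        substrate residue after which cleavage generated the product end."""
        return self.sr1[1] if self.sr2 is None else self.sr2[1]

    @property
    def sr1_length(self) -> int:
        return self.sr1[1] - self.sr1[0] + 1

    @property
    def sr2_length(self) -> int | None:
        if self.sr2 is None:
            return None
        return self.sr2[1] - self.sr2[0] + 1

    def sequence(self, substrate: Substrate) -> str:
        """Reconstruct the product sequence from the substrate."""
        s = substrate.segment(*self.sr1)
        if self.sr2 is not None:
            s += substrate.segment(*self.sr2)
        return s


def _check_length_range(min_len: int, max_len: int) -> None:
    if min_len < 1 or max_len < min_len:
        raise ValueError(f"empty or invalid length range [{min_len}, {max_len}]")


def enumerate_nonspliced(
    substrate: Substrate, min_len: int = 8, max_len: int = 12
) -> list[tuple[str, Decomposition]]:
    """All contiguous substrate fragments with length in [min_len, max_len].

    Exhaustive at the coordinate level: identical sequences arising from
    different intervals are distinct entries.
    """
    _check_length_range(min_len, max_len)
    lo, hi = substrate.first_position, substrate.last_position
    out: list[tuple[str, Decomposition]] = []
    for i in range(lo, hi + 1):
        for j in range(i + min_len - 1, min(i + max_len - 1, hi) + 1):
            d = Decomposition(NON_SPLICED, (i, j))
            out.append((d.sequence(substrate), d))
    return out


def _interval_pairs(
    substrate: Substrate,
    min_len: int,
    max_len: int,
    min_sr_len: int,
    include_reverse: bool,
) -> Iterator[Decomposition]:
    lo, hi = substrate.first_position, substrate.last_position
    for i1 in range(lo, hi + 1):
        for j1 in range(i1 + min_sr_len - 1, hi + 1):
            len1 = j1 - i1 + 1
            if len1 + min_sr_len > max_len:
                break
            for i2 in range(lo, hi + 1):
                for j2 in range(i2 + min_sr_len - 1, hi + 1):
                    total = len1 + (j2 - i2 + 1)
                    if total > max_len:
                        break
                    if total < min_len:
                        continue
                    if j1 < i2:
                        yield Decomposition(CIS_NORMAL, (i1, j1), (i2, j2))
                    elif j2 < i1 and include_reverse:
                        yield Decomposition(CIS_REVERSE, (i1, j1), (i2, j2))


def enumerate_cis(
    substrate: Substrate,
    min_len: int = 8,
    max_len: int = 12,
    include_reverse: bool = True,
    min_sr_len: int = 1,
) -> list[tuple[str, Decomposition]]:
    """All cis-spliced products (ordered disjoint interval pairs).

    Normal-order products (sr1 before sr2 in the substrate) are always
    enumerated; reverse-order products only when ``include_reverse``.
    ``min_sr_len`` is the minimum splice-reactant length (default 1).
    """
    _check_length_range(min_len, max_len)
    if min_sr_len < 1:
        raise ValueError("min_sr_len must be >= 1")
    return [
        (d.sequence(substrate), d)
        for d in _interval_pairs(substrate, min_len, max_len, min_sr_len, include_reverse)
    ]


def find_occurrences(needle: str, haystack: str) -> list[int]:
    """0-based start indices of all (possibly overlapping) occurrences."""
    out = []
    start = 0
    while True:
        k = haystack.find(needle, start)
        if k < 0:
            return out
        out.append(k)
        start = k + 1


def map_peptide(
    peptide: str, substrate: Substrate, min_sr_len: int = 1
) -> list[Decomposition]:
    """All decompositions of ``peptide`` against ``substrate``.

    Returns every non-spliced match, every cis decomposition (normal and
    reverse order), and every overlap-requiring two-segment decomposition
    (trans, i.e. needing two copies of the substrate).  A peptide that
    cannot be built from at most two substrate segments yields an empty
    list (it is unmapped, not an error).
    """
    if len(peptide) < 2:
        raise ValueError("peptide length must be >= 2")
    seq = substrate.sequence
    off = substrate.numbering_offset
    decomps: list[Decomposition] = []
    for k in find_occurrences(peptide, seq):
        decomps.append(Decomposition(NON_SPLICED, (k + off, k + off + len(peptide) - 1)))
    for split in range(min_sr_len, len(peptide) - min_sr_len + 1):
        left, right = peptide[:split], peptide[split:]
        occ_l = find_occurrences(left, seq)
        if not occ_l:
            continue
        occ_r = find_occurrences(right, seq)
        for a in occ_l:
            i1, j1 = a + off, a + off + len(left) - 1
            for b in occ_r:
                i2, j2 = b + off, b + off + len(right) - 1
                if j1 < i2:
                    cat = CIS_NORMAL
                elif j2 < i1:
                    cat = CIS_REVERSE
                else:
                    cat = TRANS
                decomps.append(Decomposition(cat, (i1, j1), (i2, j2)))
    return decomps


def classify_peptide(decompositions: Iterable[Decomposition]) -> str:
    """Category of a peptide from its decompositions.

    Precedence non-spliced > cis > trans: a peptide is called cis only if no
    non-spliced explanation exists, and trans only if it has neither.  An
    empty decomposition list classifies as ``"unmapped"``.
    """
    cats = {d.category for d in decompositions}
    for cat in CATEGORY_PRECEDENCE:
        if cat in cats:
            return cat
    return UNMAPPED
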