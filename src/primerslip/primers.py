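"""Degenerate-primer model and slippage-susceptibility scanning.

A degenerate oligo written in IUPAC ambiguity codes encodes a mixture of
concrete primer variants.  When its 3' end anneals inside a low-complexity
region (typically a homopolymer) that continues past the binding site in the
direction of elongation, some variant can also anneal one or more bases away
from the intended site.  Such shifted-but-productive binding ("slippage")
yields amplicons whose primer footprint is shorter (forward slip, deletion
after trimming) or longer (backward slip, insertion) than the primer.

This module provides the primer/binding-site types, IUPAC matching, the
3'-anchor shifted-binding rule, and per primer x template slip assessment,
including the design diagnostics that predict susceptibility: the in-site
homopolymer run at the 3' terminus, its extension into the flank, and
whether the primer carries two distinct 3'-terminal bases (a clamp).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import reverse_complement

__all__ = [
    "IUPAC_CODES",
    "DegeneratePrimer",
    "BindingSite",
    "SlipAssessment",
    "expand_degenerate",
    "degeneracy",
    "iupac_match",
    "homopolymer_run",
    "anchor_matches_at",
    "feasible_slips",
    "three_prime_distinct",
    "find_binding_site",
    "susceptibility_report",
    "DEFAULT_WINDOW",
    "DEFAULT_ANCHOR_LEN",
]

#: IUPAC nucleotide ambiguity codes mapped to the set of concrete bases each denotes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

CONCRETE_BASES = frozenset("ACGT")

#: Default slip search window (max insertion 1 nt, max deletion 4 nt).
DEFAULT_WINDOW: tuple[int, int] = (-1, 4)

#: Default 3'-terminal anchor length (nt) required to match at a shifted position.
DEFAULT_ANCHOR_LEN: int = 5


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC oligo, written 5'->3', with its PCR orientation.

    Parameters
    ----------
    name : str
        Primer identifier (e.g. ``BF1``, ``fwhR2``).
    sequence : str
        5'->3' sequence over the 15 IUPAC nucleotide codes.
    orientation : {"forward", "reverse"}
        Which strand the primer initiates synthesis on.
    """

    name: str
    sequence: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        for i, ch in enumerate(seq):
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"primer {self.name!r}: non-IUPAC character {ch!r} at position {i}"
                )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"primer {self.name!r}: orientation must be 'forward' or 'reverse', "
                f"got {self.orientation!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingSite:
    """Located primer binding site on a template.

    Coordinates are 0-based, half-open, on the strand the primer anneals to
    (i.e. the strand on which the primer sequence reads 5'->3' left to
    right).  ``start`` is the offset of the primer 5' end; the site spans
    ``[start, start + expected_footprint)``.
    """

    template_id: str
    start: int
    strand: str = "+"
    expected_footprint: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("site start must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.expected_footprint <= 0:
            raise ValueError("expected_footprint must be positive")

    @property
    def end(self) -> int:
        return self.start + self.expected_footprint


@dataclass(frozen=True)
class SlipAssessment:
    """Feasible signed slip offsets plus design diagnostics for one primer x template.

    Sign convention: ``+s`` means the primer 3' end is shifted ``s`` nt in the
    elongation direction, producing an ``s`` nt deletion in the trimmed
    amplicon; ``-s`` is a shift away from elongation, producing an insertion.
    """

    feasible: tuple[int, ...]
    anchor_len: int
    run_in_site: int
    run_extension: int
    distinct_3prime: bool
    primer_name: str = ""
    template_id: str = ""

    @property
    def class_label(self) -> str:
        has_del = any(s > 0 for s in self.feasible)
        has_ins = any(s < 0 for s in self.feasible)
        if has_del and has_ins:
            return "both"
        if has_del:
            return "deletion_prone"
        if has_ins:
            return "insertion_prone"
        return "none"

    @property
    def max_forward_slip(self) -> int:
        """Largest feasible deletion offset (0 if none)."""
        return max((s for s in self.feasible if s > 0), default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "feasible", tuple(sorted(self.feasible)))
        if 0 not in self.feasible:
            raise ValueError("slip 0 must always be feasible for a valid site")


def expand_degenerate(primer: DegeneratePrimer | str) -> set[str]:
    """Expand an IUPAC oligo into the full set of concrete ACGT variants.

    The cardinality equals the product of the per-position code sizes.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.upper()
    pools = []
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
        pools.append(sorted(IUPAC_CODES[ch]))
    return {"".join(p) for p in itertools.product(*pools)}


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of concrete variants encoded by the oligo (analytic product)."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.upper()
    n = 1
    for ch in seq:
        n *= len(IUPAC_CODES[ch])
    return n


def iupac_match(code: str, base: str) -> bool:
    """True iff concrete ``base`` is in the set denoted by IUPAC ``code``.

    The first argument is the (possibly degenerate) primer code, the second
    the concrete template base; passing an ambiguous code as ``base`` is an
    argument-order error and is rejected.
    """
    code = code.upper()
    base = base.upper()
    if code not in IUPAC_CODES:
        raise ValueError(f"{code!r} is not an IUPAC nucleotide code")
    if base not in CONCRETE_BASES:
        raise ValueError(
            f"template base must be concrete (ACGT), got {base!r}; "
            "did you swap the code/base arguments?"
        )
    return base in IUPAC_CODES[code]


def homopolymer_run(seq: str, pos: int, direction: int = 1) -> int:
    """Length of the maximal single-base run starting at ``pos`` going in ``direction``.

    ``direction`` is +1 (rightward, toward the 3' flank) or -1.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if not 0 <= pos < len(seq):
        raise ValueError(f"pos {pos} out of range for sequence of length {len(seq)}")
    base = seq[pos]
    n = 0
    i = pos
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += direction
    return n


def anchor_matches_at(
    primer: DegeneratePrimer,
    template: str,
    site: BindingSite,
    slip: int,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> bool:
    """Can some variant's 3'-terminal anchor anneal at the site shifted by ``slip``?

    The primer is shifted whole by ``slip`` (positive = elongation direction)
    and only its 3'-terminal ``anchor_len`` bases are required to match the
    template, position by position, under IUPAC semantics.  Because IUPAC
    positions are independent, "some expanded variant matches everywhere"
    is equivalent to "every anchor position's code admits the template base".
    A shifted anchor that falls outside the template is a non-match, not an
    error.
    """
    L = len(primer)
    if anchor_len < 1 or anchor_len > L:
        raise ValueError(f"anchor_len must be in [1, {L}], got {anchor_len}")
    lo = site.start + slip + L - anchor_len
    hi = site.start + slip + L
    if lo < 0 or hi > len(template):
        warnings.warn(
            f"shifted anchor (slip {slip:+d}) outside template "
            f"{site.template_id!r}; treated as non-binding",
            stacklevel=2,
        )
        return False
    for i in range(anchor_len):
        if not iupac_match(primer.sequence[L - anchor_len + i], template[lo + i]):
            return False
    return True


def _full_match_at(primer: DegeneratePrimer, template: str, start: int) -> bool:
    L = len(primer)
    if start < 0 or start + L > len(template):
        return False
    return all(iupac_match(primer.sequence[i], template[start + i]) for i in range(L))


def three_prime_distinct(primer: DegeneratePrimer) -> bool:
    """True iff every expanded variant ends in two *different* bases.

    This is the clamp rule: a primer whose last two positions can never
    realize the same base (e.g. a literal ``GC`` clamp) cannot anchor on a
    homopolymer continuation, which protects against slippage.  Every pair
    differs iff the two terminal code sets are disjoint.
    """
    if len(primer) < 2:
        raise ValueError("primer must be at least 2 nt for the 3'-end rule")
    last, second = primer.sequence[-1], primer.sequence[-2]
    return not (IUPAC_CODES[last] & IUPAC_CODES[second])


def feasible_slips(
    primer: DegeneratePrimer,
    template: str,
    site: BindingSite,
    window: tuple[int, int] = DEFAULT_WINDOW,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> SlipAssessment:
    """Assess which slip offsets are feasible for a primer on its binding site.

    Parameters
    ----------
    template : str
        Template sequence on the strand the primer anneals to (reverse
        primers: pass the reverse-complemented template and a site located
        on it).
    window : (int, int)
        Inclusive search window ``(-max_insertion, +max_deletion)``; must
        contain 0.
    anchor_len : int
        3'-terminal bases that must match at a shifted position.

    Returns
    -------
    SlipAssessment
        Feasible offsets (0 always included), homopolymer diagnostics and
        the clamp flag.
    """
    lo, hi = window
    if lo > 0 or hi < 0:
        raise ValueError(f"slip window {window} must contain 0")
    if site.end > len(template):
        raise ValueError("binding site extends beyond template")
    if not _full_match_at(primer, template, site.start):
        raise ValueError(
            f"no variant of primer {primer.name!r} matches template "
            f"{site.template_id!r} at slip 0: invalid site"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feas = [
            s
            for s in range(lo, hi + 1)
            if anchor_matches_at(primer, template, site, s, anchor_len)
        ]

    three_end = site.end - 1  # template position under the primer 3' terminus
    run_base = template[three_end]
    run_in_site = min(homopolymer_run(template, three_end, -1), site.expected_footprint)
    run_extension = 0
    j = site.end
    while j < len(template) and template[j] == run_base:
        run_extension += 1
        j += 1

    return SlipAssessment(
        feasible=tuple(feas),
        anchor_len=anchor_len,
        run_in_site=run_in_site,
        run_extension=run_extension,
        distinct_3prime=three_prime_distinct(primer),
        primer_name=primer.name,
        template_id=site.template_id,
    )


def find_binding_site(
    primer: DegeneratePrimer, template_id: str, template: str
) -> tuple[BindingSite, str] | None:
    """Locate the primer's slip-0 binding site on a template.

    Returns the site together with the template oriented to the primer's
    annealing strand (reverse primers are assessed on the reverse
    complement), or ``None`` when no full-length IUPAC match exists.
    Scanning takes the leftmost full-length match on the oriented strand.
    """
    oriented = (
        template.upper()
        if primer.orientation == "forward"
        else reverse_complement(template.upper())
    )
    L = len(primer)
    for start in range(len(oriented) - L + 1):
        if _full_match_at(primer, oriented, start):
            strand = "+" if primer.orientation == "forward" else "-"
            return (
                BindingSite(
                    template_id=template_id,
                    start=start,
                    strand=strand,
                    expected_footprint=L,
                ),
                oriented,
            )
    return None


def susceptibility_report(
    primers: Sequence[DegeneratePrimer],
    templates: Iterable[tuple[str, str]],
    sites: dict[tuple[str, str], BindingSite] | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> pd.DataFrame:
    """Scan every primer against every template and tabulate slip susceptibility.

    ``templates`` yields ``(template_id, sequence)`` pairs (top strand).
    Sites may be given per ``(primer_name, template_id)``; otherwise the
    leftmost full-length IUPAC match on the primer's strand is used.
    Templates with no slip-0 match are kept as rows flagged ``unalignable``
    rather than dropped.  Rows are ordered by (primer, template_id).
    """
    template_list = list(templates)
    rows = []
    for primer in primers:
        for template_id, seq in template_list:
            key = (primer.name, template_id)
            if sites is not None and key in sites:
                site = sites[key]
                oriented = (
                    seq.upper()
                    if primer.orientation == "forward"
                    else reverse_complement(seq.upper())
                )
                located: tuple[BindingSite, str] | None = (site, oriented)
            else:
                located = find_binding_site(primer, template_id, seq)
            if located is None:
                rows.append(
                    {
                        "primer": primer.name,
                        "template_id": template_id,
                        "feasible_slips": "",
                        "run_in_site": pd.NA,
                        "run_extension": pd.NA,
                        "distinct_3prime": three_prime_distinct(primer),
                        "class_label": "unalignable",
                    }
                )
                continue
            site, oriented = located
            a = feasible_slips(primer, oriented, site, window=window, anchor_len=anchor_len)
            rows.append(
                {
                    "primer": primer.name,
                    "template_id": template_id,
                    "feasible_slips": ",".join(str(s) for s in a.feasible),
                    "run_in_site": a.run_in_site,
                    "run_extension": a.run_extension,
                    "distinct_3prime": a.distinct_3prime,
                    "class_label": a.class_label,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "primer",
            "template_id",
            "feasible_slips",
            "run_in_site",
            "run_extension",
            "distinct_3prime",
            "class_label",
        ],
    )
    if len(df):
        df = df.sort_values(["primer", "template_id"], kind="stable").reset_index(drop=True)
    else:
        warnings.warn("susceptibility_report: no templates provided; empty report")
    return df
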