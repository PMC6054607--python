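"""Amplicon length-variation detection: the slippage analysis proper.

The analysis takes merged (or paired) amplicon reads that still carry the
incorporated primers, plus the known haplotype of each taxon.  Reads are
anchored to the unique haplotype whose full inter-primer core occurs as an
exact, gap-free substring (a 100%-identity, zero-gap mapping criterion);
the bases between the read terminus and the anchored core are the apparent
primer footprint.  Per taxon, the footprint length distribution is built,
rare overlong artifacts are excluded, a taxon is called *affected* when at
least 10% of its retained reads deviate from the expected footprint, and a
two-sided Welch t-test compares per-taxon proportions between affected and
unaffected groups.  Output mirrors a primer-summary table (length-variation
range, mean proportion at expected length +/- SD as percent, p value or NA)
and per-taxon footprint histograms with relative abundances.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from scipy import stats

from .primers import DegeneratePrimer, find_binding_site

__all__ = [
    "FootprintDistribution",
    "SlippageCallTable",
    "merge_pairs",
    "HaplotypeIndex",
    "assign_and_anchor",
    "footprint_length",
    "build_distribution",
    "classify_affected",
    "slippage_ttest",
    "summarize_primer",
    "run_detection",
    "format_pct",
]

DEFAULT_AFFECTED_THRESHOLD = 0.10
DEFAULT_ARTIFACT_MARGIN = 2
ARTIFACT_CEILING = 3  # warn when a taxon exceeds this many excluded artifacts


def merge_pairs(
    r1_seq: str,
    r1_qual: str,
    r2_seq: str,
    r2_qual: str,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.10,
) -> tuple[str, str] | None:
    """Merge a read pair by exact overlap search; None on failure.

    R2 is reverse-complemented, then the longest 3'(R1)/5'(R2) overlap of at
    least ``min_overlap`` bases whose mismatch fraction is at most
    ``max_mismatch_frac`` (inclusive, i.e. 90% identity passes) is taken.
    Disagreeing overlap bases are resolved toward the higher quality symbol.
    """
    if len(r1_seq) != len(r1_qual) or len(r2_seq) != len(r2_qual):
        raise ValueError("sequence/quality length mismatch in read pair")
    rc2 = reverse_complement(r2_seq)
    rq2 = r2_qual[::-1]
    max_o = min(len(r1_seq), len(rc2))
    for o in range(max_o, min_overlap - 1, -1):
        a = r1_seq[-o:]
        b = rc2[:o]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism <= max_mismatch_frac * o + 1e-9:
            merged = []
            qual = []
            qa = r1_qual[-o:]
            qb = rq2[:o]
            for x, y, px, py in zip(a, b, qa, qb):
                if x == y or px >= py:
                    merged.append(x)
                    qual.append(max(px, py))
                else:
                    merged.append(y)
                    qual.append(py)
            return (
                r1_seq[:-o] + "".join(merged) + rc2[o:],
                r1_qual[:-o] + "".join(qual) + rq2[o:],
            )
    return None


class HaplotypeIndex:
    """Reference haplotypes with precomputed inter-primer cores.

    The core of each haplotype — the region strictly between the forward
    and reverse primer binding sites — is the exact-match anchoring key.
    A configurable prefix length accelerates the substring scan (candidate
    hits on the first ``anchor_prefix`` bases are verified against the full
    core, so results are identical to a full-core scan).
    """

    def __init__(
        self,
        haplotypes: dict[str, str],
        primer_fwd: DegeneratePrimer,
        primer_rev: DegeneratePrimer,
        anchor_prefix: int | None = 30,
    ) -> None:
        if len(set(haplotypes)) != len(haplotypes):
            raise ValueError("duplicate taxon_ids in references")
        self.cores: dict[str, str] = {}
        self.expected_fwd = len(primer_fwd)
        self.expected_rev = len(primer_rev)
        self.anchor_prefix = anchor_prefix
        for tid, seq in haplotypes.items():
            seq = seq.upper()
            fwd = find_binding_site(primer_fwd, tid, seq)
            rev = find_binding_site(primer_rev, tid, seq)
            if fwd is None or rev is None:
                raise ValueError(f"haplotype {tid!r}: primer binding site not found")
            fwd_site, _ = fwd
            rev_site, _ = rev
            rev_start_top = len(seq) - rev_site.end  # convert from rc coordinates
            core = seq[fwd_site.end: rev_start_top]
            if not core:
                raise ValueError(f"haplotype {tid!r}: empty inter-primer core")
            self.cores[tid] = core
        dups = Counter(self.cores.values())
        self._n_core_owners = {core: n for core, n in dups.items()}

    def _find_core(self, read: str, core: str) -> int:
        if self.anchor_prefix is None or len(core) <= self.anchor_prefix:
            return read.find(core)
        prefix = core[: self.anchor_prefix]
        pos = read.find(prefix)
        while pos != -1:
            if read.startswith(core, pos):
                return pos
            pos = read.find(prefix, pos + 1)
        return -1


def assign_and_anchor(
    read: str, index: HaplotypeIndex
) -> tuple[str, int, int, str] | str:
    """Assign a read to the unique taxon whose core it contains exactly.

    Returns ``(taxon_id, core_start, core_end, orientation)`` with
    coordinates on the forward-oriented read, or the string ``"unassigned"``
    (no exact core) / ``"ambiguous"`` (cores of two or more taxa found).
    A single substitution inside the core makes the read unassigned — the
    mapping criterion is 100% identity with zero gaps.
    """
    read = read.upper()
    rc = reverse_complement(read)
    hits: list[tuple[str, int, str]] = []
    for tid, core in index.cores.items():
        pos = index._find_core(read, core)
        if pos != -1:
            hits.append((tid, pos, "+"))
            continue
        pos = index._find_core(rc, core)
        if pos != -1:
            hits.append((tid, pos, "-"))
    if not hits:
        return "unassigned"
    if len(hits) > 1:
        return "ambiguous"
    tid, pos, orient = hits[0]
    core_len = len(index.cores[tid])
    if orient == "-":
        # report coordinates on the forward-oriented (as-anchored) read
        return (tid, pos, pos + core_len, "-")
    return (tid, pos, pos + core_len, "+")


def footprint_length(read: str, core_start: int, core_end: int | None = None,
                     end: str = "forward") -> int:
    """Apparent primer footprint: the read overhang outside the anchored core.

    ``end="forward"`` returns the 5' overhang (bases before the core);
    ``end="reverse"`` the 3' overhang.  An overhang of 0 is valid.
    """
    if end == "forward":
        if core_start < 0:
            raise ValueError("negative core_start")
        return core_start
    if end == "reverse":
        if core_end is None:
            raise ValueError("core_end required for the reverse footprint")
        return len(read) - core_end
    raise ValueError("end must be 'forward' or 'reverse'")


@dataclass
class FootprintDistribution:
    """Per-taxon histogram of apparent primer footprint lengths."""

    taxon_id: str
    expected_len: int
    histogram: dict[int, int] = field(default_factory=dict)
    n_assigned: int = 0
    n_artifact: int = 0
    n_retained: int = 0

    @property
    def prop_expected(self) -> float:
        """Fraction of retained reads whose footprint equals the primer length."""
        if self.n_retained == 0:
            return float("nan")
        return self.histogram.get(self.expected_len, 0) / self.n_retained

    @property
    def n_deviating(self) -> int:
        return self.n_retained - self.histogram.get(self.expected_len, 0)

    def observed_offsets(self) -> list[int]:
        """Signed length deviations (footprint − expected) present in the data."""
        return sorted(l - self.expected_len for l in self.histogram if l != self.expected_len)


def build_distribution(
    footprints,
    taxon_id: str,
    expected_len: int,
    artifact_margin: int = DEFAULT_ARTIFACT_MARGIN,
) -> FootprintDistribution:
    """Histogram footprints, excluding much-longer-than-expected artifacts.

    Footprints more than ``artifact_margin`` nt above the expected length
    are sequencing artifacts and are excluded (counted); single-base
    insertions (+1, +2 window) are genuine signal and retained, as are all
    shorter footprints.  A warning is emitted when a taxon exceeds the
    usual artifact ceiling of three.
    """
    if expected_len <= 0:
        raise ValueError("expected_len must be positive")
    hist: Counter[int] = Counter()
    n_art = 0
    n_in = 0
    for f in footprints:
        n_in += 1
        if f > expected_len + artifact_margin:
            n_art += 1
        else:
            hist[f] += 1
    if n_art > ARTIFACT_CEILING:
        warnings.warn(
            f"taxon {taxon_id!r}: {n_art} overlong artifacts excluded "
            f"(more than the usual ceiling of {ARTIFACT_CEILING})",
            stacklevel=2,
        )
    return FootprintDistribution(
        taxon_id=taxon_id,
        expected_len=expected_len,
        histogram=dict(sorted(hist.items())),
        n_assigned=n_in,
        n_artifact=n_art,
        n_retained=n_in - n_art,
    )


def classify_affected(
    dist: FootprintDistribution, threshold: float = DEFAULT_AFFECTED_THRESHOLD
) -> bool | None:
    """True when ``threshold`` (default 10%) or more retained reads deviate.

    The boundary is inclusive: exactly 10% deviating reads is affected.
    Returns None (undefined) for a taxon with no retained reads; such taxa
    are excluded from grouping.
    """
    if dist.n_retained == 0:
        return None
    return dist.n_deviating >= threshold * dist.n_retained - 1e-9


def slippage_ttest(props_affected, props_unaffected) -> float | None:
    """Two-sided Welch t-test on per-taxon proportions between groups.

    Undefined (None) when either group is empty — no slippage/no-slippage
    contrast exists — or has a single member (variance undefined).
    """
    a = np.asarray(list(props_affected), float)
    b = np.asarray(list(props_unaffected), float)
    if len(a) == 0 or len(b) == 0:
        return None
    if len(a) == 1 or len(b) == 1:
        warnings.warn("t-test undefined for a group of size 1", stacklevel=2)
        return None
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    with warnings.catch_warnings():
        # a zero-variance group (e.g. all taxa at exactly 100%) is a valid
        # degenerate Welch case; silence scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def format_pct(x: float, decimals: int = 2) -> str:
    """Percent with fixed decimals, half-even rounding (table formatting)."""
    from decimal import ROUND_HALF_EVEN, Decimal

    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class SlippageCallTable:
    """Per-primer summary: per-taxon calls plus the group statistics row."""

    primer: str
    calls: pd.DataFrame  # taxon_id, n_retained, prop_expected, affected
    variation_range: str
    mean_prop_expected: float  # over all analyzed taxa, as a fraction
    sd_prop_expected: float
    t_test_p: float | None

    def summary_row(self) -> dict:
        return {
            "primer": self.primer,
            "variation_range": self.variation_range,
            "mean_prop_expected_pct": format_pct(100 * self.mean_prop_expected),
            "sd_pct": format_pct(100 * self.sd_prop_expected),
            "t_test_p": "NA" if self.t_test_p is None else f"{self.t_test_p:.3g}",
        }


def summarize_primer(
    distributions: list[FootprintDistribution],
    primer_name: str = "primer",
    threshold: float = DEFAULT_AFFECTED_THRESHOLD,
) -> tuple[SlippageCallTable, pd.DataFrame]:
    """Aggregate per-taxon distributions into the summary row and histograms.

    The summary gives the observed length-variation range (signed
    footprint − expected deviations; "No variation" when every retained
    read is at the expected length), the mean ± SD of per-taxon proportions
    at expected length over ALL analyzed taxa (percent), and the Welch
    p value between affected and unaffected groups (NA when only one group
    exists).  The histogram table carries per-taxon footprint-length
    percentages summing to 100.
    """
    if not distributions:
        raise ValueError("at least one taxon required")
    analyzed = [d for d in distributions if d.n_retained > 0]
    call_rows = []
    all_offsets: set[int] = set()
    for d in analyzed:
        aff = classify_affected(d, threshold)
        call_rows.append(
            {
                "taxon_id": d.taxon_id,
                "n_retained": d.n_retained,
                "prop_expected": d.prop_expected,
                "affected": aff,
            }
        )
        all_offsets.update(d.observed_offsets())
    calls = pd.DataFrame(call_rows, columns=["taxon_id", "n_retained", "prop_expected", "affected"])

    if all_offsets:
        lo, hi = min(all_offsets), max(all_offsets)
        variation_range = f"{lo} to {hi} bp"
    else:
        variation_range = "No variation"

    props = calls["prop_expected"].to_numpy(float)
    mean = float(props.mean()) if len(props) else float("nan")
    sd = float(props.std(ddof=1)) if len(props) > 1 else 0.0
    p = slippage_ttest(
        props[calls["affected"].to_numpy(bool)],
        props[~calls["affected"].to_numpy(bool)],
    )

    hist_rows = []
    for d in analyzed:
        for length, count in sorted(d.histogram.items()):
            hist_rows.append(
                {
                    "taxon": d.taxon_id,
                    "footprint_len": length,
                    "count": count,
                    "percent": 100.0 * count / d.n_retained,
                }
            )
    histograms = pd.DataFrame(hist_rows, columns=["taxon", "footprint_len", "count", "percent"])

    table = SlippageCallTable(
        primer=primer_name,
        calls=calls,
        variation_range=variation_range,
        mean_prop_expected=mean,
        sd_prop_expected=sd,
        t_test_p=p,
    )
    return table, histograms


def run_detection(
    reads,
    haplotypes: dict[str, str],
    primer_fwd: DegeneratePrimer,
    primer_rev: DegeneratePrimer,
    mode: str = "forward",
    threshold: float = DEFAULT_AFFECTED_THRESHOLD,
    artifact_margin: int = DEFAULT_ARTIFACT_MARGIN,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.10,
    top_n: int | None = None,
) -> dict:
    """Full analysis on merged reads or read pairs.

    ``reads``: an iterable of ``(id, seq, qual)`` merged reads or of
    ``((id, seq, qual), (id, seq, qual))`` pairs (merged internally).
    ``mode``: measure the "forward" footprint (5' overhang), or "both".
    ``top_n``: optionally restrict the analysis to the N taxa with the most
    assigned reads (mirrors selecting the most abundant OTUs).

    Returns a dict with the call table(s), histograms and full accounting
    (input reads = merge failures + unassigned + ambiguous + assigned;
    per taxon, assigned = artifact + retained).
    """
    index = HaplotypeIndex(haplotypes, primer_fwd, primer_rev)
    fwd_foot: dict[str, list[int]] = {tid: [] for tid in index.cores}
    rev_foot: dict[str, list[int]] = {tid: [] for tid in index.cores}
    n_input = n_merge_failed = n_unassigned = n_ambiguous = 0

    def _seq_qual(r):
        if hasattr(r, "sequence"):
            return r.sequence, r.quality
        return r[1], r[2]

    for item in reads:
        n_input += 1
        if hasattr(item, "sequence"):
            seq = item.sequence
        elif len(item) == 2 and (
            hasattr(item[0], "sequence")
            or (isinstance(item[0], (tuple, list)) and len(item[0]) == 3)
        ):
            s1, q1 = _seq_qual(item[0])
            s2, q2 = _seq_qual(item[1])
            merged = merge_pairs(s1, q1, s2, q2, min_overlap, max_mismatch_frac)
            if merged is None:
                n_merge_failed += 1
                continue
            seq = merged[0]
        else:
            seq = item[1]
        res = assign_and_anchor(seq, index)
        if res == "unassigned":
            n_unassigned += 1
            continue
        if res == "ambiguous":
            n_ambiguous += 1
            continue
        tid, start, end, orient = res
        oriented = seq if orient == "+" else reverse_complement(seq)
        fwd_foot[tid].append(footprint_length(oriented, start, end, end="forward"))
        if mode == "both":
            rev_foot[tid].append(footprint_length(oriented, start, end, end="reverse"))

    if top_n is not None:
        keep = sorted(fwd_foot, key=lambda t: len(fwd_foot[t]), reverse=True)[:top_n]
        fwd_foot = {t: fwd_foot[t] for t in keep}
        rev_foot = {t: rev_foot[t] for t in keep}

    dists = [
        build_distribution(fwd_foot[tid], tid, index.expected_fwd, artifact_margin)
        for tid in sorted(fwd_foot)
    ]
    table, histograms = summarize_primer(dists, primer_fwd.name, threshold)
    out = {
        "table": table,
        "histograms": histograms,
        "distributions": {d.taxon_id: d for d in dists},
        "accounting": {
            "n_input": n_input,
            "n_merge_failed": n_merge_failed,
            "n_unassigned": n_unassigned,
            "n_ambiguous": n_ambiguous,
            "n_assigned": n_input - n_merge_failed - n_unassigned - n_ambiguous,
        },
    }
    if mode == "both":
        rdists = [
            build_distribution(rev_foot[tid], tid, index.expected_rev, artifact_margin)
            for tid in sorted(rev_foot)
        ]
        rtable, rhist = summarize_primer(rdists, primer_rev.name, threshold)
        out["table_reverse"] = rtable
        out["histograms_reverse"] = rhist
        out["distributions_reverse"] = {d.taxon_id: d for d in rdists}
    return out
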