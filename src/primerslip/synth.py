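"""Synthetic mock communities with engineered primer-slippage behavior.

Real tests of slippage detection need templates whose binding sites differ
in exactly the features that drive slippage: the length of the 3'-terminal
homopolymer inside the binding site, how far that run continues into the
flank in the elongation direction, whether an interrupting base terminates
it, and whether a tandem repeat straddles the site/flank junction.  This
module builds haplotypes from such specifications, whole communities with a
chosen mix of slip-prone and protected taxa, and FASTQ reads (merged or
paired) from simulated amplicon pools — all with recomputable ground truth.

Core sequences are i.i.d. uniform ACGT with homopolymer runs of 5+ rejected
outside the engineered site, so the engineered region is the only
low-complexity stretch and read anchoring is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .primers import (
    DEFAULT_ANCHOR_LEN,
    DEFAULT_WINDOW,
    IUPAC_CODES,
    BindingSite,
    DegeneratePrimer,
    SlipAssessment,
    feasible_slips,
)
from .simulate import AmpliconPool

__all__ = [
    "TemplateSpec",
    "ReadSimConfig",
    "MockTemplate",
    "Read",
    "DEMO_FORWARD",
    "DEMO_REVERSE",
    "make_template",
    "make_community",
    "pool_to_reads",
    "slip_prone_spec",
    "protected_spec",
]

# Built-in demo primer pair for community generation.  The forward primer's
# five 3'-terminal codes all admit cytosine (YCCCC) so engineered C-runs
# support shifted anchoring; it deliberately lacks a clamp.  The reverse
# primer ends in GC, the clamp pattern that blocks slippage.
DEMO_FORWARD = DegeneratePrimer("synF", "ACAGGCTGRACWGTTTAYCCCC", "forward")
DEMO_REVERSE = DegeneratePrimer("synR", "TANACYTCNGGRTGNCCGC", "reverse")

_FLANK = 8  # constant outer flank length (nt) on each template end


@dataclass(frozen=True)
class TemplateSpec:
    """Binding-site recipe for one mock haplotype.

    ``h_in`` is the engineered homopolymer length at the forward primer's 3'
    terminus inside the site; ``h_ext`` its continuation into the flanking
    (core-side) region in the elongation direction; ``interrupt`` an
    optional base terminating the run; ``tandem`` an optional repeat unit
    placed at the site/flank junction (overrides run engineering).
    """

    taxon_id: str
    core_length: int = 120
    h_in: int = 4
    h_ext: int = 2
    interrupt: str | None = None
    tandem: str | None = None
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.core_length < 50:
            raise ValueError("core_length must be >= 50")
        if self.h_in < 1:
            raise ValueError("h_in must be >= 1")
        if self.h_ext < 0:
            raise ValueError("h_ext must be >= 0")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.interrupt is not None and self.interrupt.upper() not in "ACGT":
            raise ValueError("interrupt must be a concrete base")


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters (constant quality; substitutions only).

    Indel sequencing errors are deliberately absent: terminal length
    variation must be attributable to the primers, not the sequencer.
    """

    read_length: int = 150
    mode: str = "merged"
    sub_error_rate: float = 0.0
    quality_char: str = "I"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("merged", "paired"):
            raise ValueError("mode must be 'merged' or 'paired'")
        if not 0 <= self.sub_error_rate < 0.05:
            raise ValueError("sub_error_rate must be in [0, 0.05)")
        if len(self.quality_char) != 1:
            raise ValueError("quality_char must be a single symbol")


@dataclass
class MockTemplate:
    """A generated haplotype with its parts and recomputed ground truth."""

    taxon_id: str
    sequence: str
    flank5: str
    fwd_site_seq: str
    core: str
    rev_site_top: str
    flank3: str
    run_base: str
    spec: TemplateSpec
    fwd_site: BindingSite
    fwd_assessment: SlipAssessment
    rev_assessment: SlipAssessment

    @property
    def expected_footprint(self) -> int:
        return len(self.fwd_site_seq)

    def amplicon_for_offset(self, offset: int) -> str:
        """Amplicon (primer-to-primer, top strand) for a cumulative slip offset.

        Positive offsets delete the leading bases of the core region that
        the shifted primer covered; negative offsets insert extra run
        bases ahead of the core.
        """
        if offset > 0:
            if offset > len(self.core):
                raise ValueError("offset exceeds core length")
            middle = self.core[offset:]
        elif offset < 0:
            middle = self.run_base * (-offset) + self.core
        else:
            middle = self.core
        return self.fwd_site_seq + middle + self.rev_site_top


@dataclass(frozen=True)
class Read:
    """One synthetic read (or read pair member) with constant quality."""

    read_id: str
    sequence: str
    quality: str


def _pick_base(rng: np.random.Generator, choices) -> str:
    choices = sorted(choices)
    return choices[int(rng.integers(len(choices)))]


def _random_seq(rng: np.random.Generator, n: int, avoid_start: str | None = None,
                max_run: int = 4) -> str:
    """Uniform ACGT sequence with homopolymer runs capped at ``max_run``."""
    out: list[str] = []
    bases = "ACGT"
    while len(out) < n:
        b = bases[int(rng.integers(4))]
        run = 1
        j = len(out) - 1
        while j >= 0 and out[j] == b:
            run += 1
            j -= 1
        if run > max_run:
            continue
        if not out and avoid_start is not None and b == avoid_start:
            continue
        out.append(b)
    return "".join(out)


def _concrete_site(rng: np.random.Generator, primer: DegeneratePrimer) -> list[str]:
    """One concrete realization of the primer as a template site."""
    return [_pick_base(rng, IUPAC_CODES[c]) for c in primer.sequence]


def make_template(
    spec: TemplateSpec,
    primer_fwd: DegeneratePrimer = DEMO_FORWARD,
    primer_rev: DegeneratePrimer = DEMO_REVERSE,
    seed: int = 0,
    window: tuple[int, int] = DEFAULT_WINDOW,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> MockTemplate:
    """Build one haplotype realizing the spec, with ground truth recomputed.

    The template is ``flank5 + forward site + core + reverse site + flank3``
    on the top strand.  The forward site matches the forward primer at slip
    0 and carries the engineered homopolymer / tandem features; the core's
    far end is generated so the reverse primer stays slip-protected.

    Raises ``ValueError`` when the spec is incompatible with the primer
    (e.g. the primer's 3'-terminal codes cannot realize the requested run).
    """
    rng = np.random.default_rng(seed)
    L = len(primer_fwd)
    codes = [IUPAC_CODES[c] for c in primer_fwd.sequence]

    # --- forward site ---------------------------------------------------
    site = _concrete_site(rng, primer_fwd)
    if spec.tandem:
        unit = spec.tandem.upper()
        if len(unit) >= L:
            raise ValueError("tandem unit must be shorter than the primer")
        for i, b in enumerate(unit):
            if b not in codes[L - len(unit) + i]:
                raise ValueError(
                    f"spec {spec.taxon_id!r}: primer 3' end cannot realize "
                    f"tandem unit {unit!r} (position {L - len(unit) + i})"
                )
        site[L - len(unit):] = list(unit)
        run_base = unit[-1]
        core_prefix = unit  # flank repeats the unit -> +len(unit) slip
        after = None
    else:
        if spec.h_in > L:
            raise ValueError("h_in cannot exceed primer length")
        # run base must be realizable by every code under the run
        cands = [b for b in "CGAT" if all(b in codes[L - 1 - j] for j in range(spec.h_in))]
        if not cands:
            raise ValueError(
                f"spec {spec.taxon_id!r}: no base is admitted by all "
                f"{spec.h_in} 3'-terminal codes of primer {primer_fwd.name!r}"
            )
        run_base = cands[0]
        site[L - spec.h_in:] = [run_base] * spec.h_in
        if spec.h_in < L:
            pre = IUPAC_CODES[primer_fwd.sequence[L - spec.h_in - 1]] - {run_base}
            if not pre:
                raise ValueError(
                    f"spec {spec.taxon_id!r}: code before the run only admits "
                    f"{run_base!r}; the engineered run would be longer than h_in"
                )
            site[L - spec.h_in - 1] = _pick_base(rng, pre)
        core_prefix = run_base * spec.h_ext
        if spec.interrupt:
            after = spec.interrupt.upper()
            if after == run_base:
                raise ValueError(
                    f"spec {spec.taxon_id!r}: interrupt base equals the run base"
                )
        else:
            # terminate the run with a base the primer 3' code cannot bind,
            # so feasibility stops exactly at h_ext
            stop = sorted(set("ACGT") - {run_base} - IUPAC_CODES[primer_fwd.sequence[-1]])
            after = stop[0] if stop else _pick_base(rng, set("ACGT") - {run_base})
        core_prefix += after
    fwd_site_seq = "".join(site)

    # avoid the site's terminal run bleeding backwards into the flank
    flank5 = _random_seq(rng, _FLANK, avoid_start=None)
    if flank5[-1] == fwd_site_seq[0]:
        flank5 = flank5[:-1] + _pick_base(rng, set("ACGT") - {fwd_site_seq[0]})

    # --- reverse site (slip-protected by default) -----------------------
    rev_site_seq = "".join(_concrete_site(rng, primer_rev))
    rev_site_top = reverse_complement(rev_site_seq)

    # --- core ------------------------------------------------------------
    n_rand = spec.core_length - len(core_prefix)
    if n_rand < 10:
        raise ValueError("core_length too small for the engineered prefix")
    # the reverse primer's elongation-direction flank is the reverse
    # complement of the core's tail: keep it off the reverse 3' base's run
    rev_flank_block = reverse_complement(rev_site_seq[-1])
    for _ in range(200):
        tail = _random_seq(rng, n_rand, avoid_start=(core_prefix[-1] if core_prefix else None))
        if tail[-1] == rev_flank_block:
            continue
        core = core_prefix + tail
        sequence = flank5 + fwd_site_seq + core + rev_site_top + _random_seq(rng, _FLANK)
        fwd_site = BindingSite(
            template_id=spec.taxon_id,
            start=len(flank5),
            strand="+",
            expected_footprint=L,
        )
        fwd_assessment = feasible_slips(
            primer_fwd, sequence, fwd_site, window=window, anchor_len=anchor_len
        )
        rc = reverse_complement(sequence)
        rev_start = len(rc) - (len(flank5) + L + len(core) + len(rev_site_top))
        rev_site = BindingSite(
            template_id=spec.taxon_id,
            start=rev_start,
            strand="-",
            expected_footprint=len(primer_rev),
        )
        rev_assessment = feasible_slips(
            primer_rev, rc, rev_site, window=window, anchor_len=anchor_len
        )
        if rev_assessment.feasible != (0,):
            continue  # random tail enabled reverse slippage; redraw
        # engineered intent check: protected specs must come out protected
        if spec.tandem is None and spec.h_ext == 0 and fwd_assessment.feasible != (0,):
            continue
        flank3 = sequence[len(flank5) + L + len(core) + len(rev_site_top):]
        return MockTemplate(
            taxon_id=spec.taxon_id,
            sequence=sequence,
            flank5=flank5,
            fwd_site_seq=fwd_site_seq,
            core=core,
            rev_site_top=rev_site_top,
            flank3=flank3,
            run_base=run_base,
            spec=spec,
            fwd_site=fwd_site,
            fwd_assessment=fwd_assessment,
            rev_assessment=rev_assessment,
        )
    raise RuntimeError(
        f"spec {spec.taxon_id!r}: could not realize a conforming template in 200 draws"
    )


def slip_prone_spec(taxon_id: str, h_ext: int = 2, core_length: int = 120,
                    abundance: float = 1.0) -> TemplateSpec:
    """Spec for a deletion-prone taxon: 4 nt in-site run continuing h_ext nt."""
    return TemplateSpec(taxon_id=taxon_id, core_length=core_length, h_in=4,
                        h_ext=h_ext, abundance=abundance)


def protected_spec(taxon_id: str, core_length: int = 120,
                   abundance: float = 1.0) -> TemplateSpec:
    """Spec for a protected taxon: the in-site run is interrupted immediately."""
    return TemplateSpec(taxon_id=taxon_id, core_length=core_length, h_in=4,
                        h_ext=0, abundance=abundance)


def make_community(
    n_taxa: int,
    class_mix: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    primer_fwd: DegeneratePrimer = DEMO_FORWARD,
    primer_rev: DegeneratePrimer = DEMO_REVERSE,
    core_length: int = 120,
    window: tuple[int, int] = DEFAULT_WINDOW,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> tuple[list[MockTemplate], pd.DataFrame]:
    """Generate a mock community of slip-prone and protected haplotypes.

    ``class_mix`` gives the (slip-prone, protected) fractions and must sum
    to 1.  Abundances are uniform.  Slip-prone taxa alternate between run
    extensions of 2 and 3 nt.  Deterministic under ``seed``: identical
    seeds produce byte-identical sequences.

    Returns the templates and a ground-truth table (taxon_id, class,
    feasible_slips, run_in_site, run_extension, abundance).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix fractions must sum to 1")
    n_prone = round(n_taxa * class_mix[0])
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_taxa):
        tid = f"taxon_{i + 1:02d}"
        if i < n_prone:
            specs.append(slip_prone_spec(tid, h_ext=2 + (i % 2), core_length=core_length,
                                         abundance=1.0 / n_taxa))
        else:
            specs.append(protected_spec(tid, core_length=core_length,
                                        abundance=1.0 / n_taxa))
    templates = [
        make_template(s, primer_fwd, primer_rev,
                      seed=int(rng.integers(2**31 - 1)),
                      window=window, anchor_len=anchor_len)
        for s in specs
    ]
    truth = pd.DataFrame(
        {
            "taxon_id": [t.taxon_id for t in templates],
            "class": ["slip_prone" if t.fwd_assessment.feasible != (0,) else "protected"
                      for t in templates],
            "feasible_slips": [",".join(map(str, t.fwd_assessment.feasible))
                               for t in templates],
            "run_in_site": [t.fwd_assessment.run_in_site for t in templates],
            "run_extension": [t.fwd_assessment.run_extension for t in templates],
            "abundance": [t.spec.abundance for t in templates],
        }
    )
    return templates, truth


def _apply_sub_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def pool_to_reads(
    pool: AmpliconPool,
    template: MockTemplate,
    cfg: ReadSimConfig,
    n_reads: int | None = None,
) -> tuple[list[Read] | list[tuple[Read, Read]], int]:
    """Turn a final amplicon pool into FASTQ-ready reads with known truth.

    Each molecule yields one merged read, or one read pair whose members
    overlap by at least 10 nt.  Reads contain the incorporated primer at
    the terminus, with the forward footprint shortened or lengthened by the
    molecule's cumulative offset.  ``n_reads`` resamples the pool's offset
    fractions to a fixed read count (multinomial); ``None`` emits one read
    per pooled molecule.  Returns ``(reads, n_skipped)`` where skipped
    molecules are those whose amplicon cannot satisfy the pairing overlap.
    """
    if pool.total == 0:
        raise ValueError("empty amplicon pool")
    if cfg.read_length <= template.expected_footprint + 10:
        raise ValueError("read_length must exceed primer length + 10")
    rng = np.random.default_rng(cfg.seed)
    counts = pool.counts
    offsets = sorted(counts)
    if n_reads is not None:
        probs = np.array([counts[k] for k in offsets], float)
        draws = rng.multinomial(n_reads, probs / probs.sum())
        counts = {k: int(m) for k, m in zip(offsets, draws)}

    out: list = []
    skipped = 0
    idx = 0
    for k in offsets:
        n = counts.get(k, 0)
        if n == 0:
            continue
        amplicon = template.amplicon_for_offset(k)
        if cfg.mode == "paired":
            overlap = 2 * min(cfg.read_length, len(amplicon)) - len(amplicon)
            if overlap < 10:
                skipped += n
                continue
        for _ in range(n):
            idx += 1
            rid = f"{template.taxon_id}.read{idx}"
            seq = _apply_sub_errors(amplicon, cfg.sub_error_rate, rng)
            if cfg.mode == "merged":
                out.append(Read(rid, seq, cfg.quality_char * len(seq)))
            else:
                r1 = seq[: cfg.read_length]
                r2 = reverse_complement(seq)[: cfg.read_length]
                out.append(
                    (
                        Read(rid + "/1", r1, cfg.quality_char * len(r1)),
                        Read(rid + "/2", r2, cfg.quality_char * len(r2)),
                    )
                )
    return out, skipped
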