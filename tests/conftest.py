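from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))

from primerslip import BindingSite, DegeneratePrimer
from primerslip.synth import DEMO_FORWARD, DEMO_REVERSE


@pytest.fixture
def fwd_primer() -> DegeneratePrimer:
    return DEMO_FORWARD


@pytest.fixture
def rev_primer() -> DegeneratePrimer:
    return DEMO_REVERSE


@pytest.fixture
def tandem_primer() -> DegeneratePrimer:
    """Forward primer whose 3' end can realize the tandem unit ACCC."""
    return DegeneratePrimer("tdF", "ACAGGCTGRACWGTTCACCC", "forward")


def random_primer_template(rng: np.random.Generator, max_primer=12, max_template=60):
    """A random template with a guaranteed slip-0 site and a derived primer.

    The primer is built from the template segment under the site, with some
    positions widened to a degenerate code containing the template base, so
    a full-length IUPAC match at slip 0 holds by construction.
    """
    from primerslip.primers import IUPAC_CODES

    L = int(rng.integers(6, max_primer + 1))
    tlen = int(rng.integers(L + 8, max_template + 1))
    template = "".join("ACGT"[i] for i in rng.integers(0, 4, tlen))
    # bias toward low-complexity 3' context to exercise slips
    if rng.random() < 0.7:
        run = int(rng.integers(2, 7))
        base = "ACGT"[int(rng.integers(4))]
        start = int(rng.integers(0, tlen - L - 5))
        pos = start + L - int(rng.integers(1, 4))
        template = template[:pos] + base * run + template[pos + run:]
        template = template[:tlen]
    start = int(rng.integers(0, tlen - L - 4))
    primer_chars = []
    for i in range(L):
        b = template[start + i]
        if rng.random() < 0.3:
            choices = [c for c, s in IUPAC_CODES.items() if b in s and len(s) > 1]
            primer_chars.append(choices[int(rng.integers(len(choices)))])
        else:
            primer_chars.append(b)
    primer = DegeneratePrimer(f"rnd", "".join(primer_chars), "forward")
    site = BindingSite(template_id="tpl", start=start, strand="+", expected_footprint=L)
    return primer, template, site
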