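"""Shared fixtures: tiny genomes and hand-built pileup tables."""

import numpy as np
import pytest

from regenmut.io import Genome, PileupCell, PileupSite, PileupTable


@pytest.fixture
def toy_genome() -> Genome:
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    return Genome({
        "s1": "".join(rng.choice(bases, size=400)),
        "s2": "".join(rng.choice(bases, size=300)),
    })


def make_cell(depth: int, ref: str, alt: str = None, alt_count: int = 0,
              mq: float = 60.0, extra: dict = None) -> PileupCell:
    counts = dict(extra or {})
    if alt is not None and alt_count:
        counts[alt] = counts.get(alt, 0) + alt_count
    counts[ref] = depth - sum(counts.values())
    return PileupCell(depth=depth, counts={k: v for k, v in counts.items() if v},
                      mean_mq=mq)


def make_site(scaffold: str, pos0: int, ref: str, cells: dict) -> PileupSite:
    return PileupSite(scaffold=scaffold, pos0=pos0, ref=ref, cells=cells)


def single_site_table(samples, ref: str, cells: dict, scaffold="s1",
                      pos0=100) -> PileupTable:
    return PileupTable(samples=list(samples),
                       sites=[make_site(scaffold, pos0, ref, cells)])
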