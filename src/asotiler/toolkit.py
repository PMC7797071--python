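"""Design summaries, digestion-fragment prediction, reaction stoichiometry,
and synthetic fixtures.

The synthetic generators stand in for rRNA targets in tests and examples:
uniform-composition random RNA at a requested GC content, and divergent
variant pairs differing by uniformly placed substitutions (no indels), as
for the ~86%-similar maternal/somatic rRNA variant pairs a shared pool must
cover. Real rRNA differs in having strongly block-structured conservation
and biased composition; see docs/methods.md for what that implies about
test coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .multitarget import Alignment, SharedDesign
from .tiler import TargetSeq, TilingResult, tile_end_to_end

__all__ = [
    "DesignSummary",
    "summarize_design",
    "predicted_fragment_lengths",
    "target_molarity",
    "make_synthetic_target",
    "make_divergent_pair",
]


def _results_of(design) -> List[TilingResult]:
    if isinstance(design, SharedDesign):
        return list(design.per_target.values())
    if isinstance(design, TilingResult):
        return [design]
    return list(design)


def _distinct_oligos(design):
    seen = {}
    for res in _results_of(design):
        for o in res.oligos:
            seen.setdefault(o.id, o)
    return list(seen.values())


@dataclass(frozen=True)
class DesignSummary:
    """Counts, coverage and cost of a design, with an optional end-to-end
    50-mer baseline for comparison. Costs keep full precision; display
    rounding is to the nearest whole currency unit."""

    n_oligos: int
    bases_tiled: int
    total_target_bases: int
    fraction_tiled: float
    cost: float
    baseline_n_oligos: Optional[int] = None
    baseline_bases: Optional[int] = None
    baseline_cost: Optional[float] = None
    percent_cost_reduction: Optional[float] = None

    @property
    def cost_display(self) -> int:
        return round(self.cost)

    @property
    def baseline_cost_display(self) -> Optional[int]:
        return None if self.baseline_cost is None else round(self.baseline_cost)

    @property
    def percent_cost_reduction_display(self) -> Optional[int]:
        return None if self.percent_cost_reduction is None else round(self.percent_cost_reduction)


def summarize_design(design, unit_price: float = 0.0,
                     baseline_unit_price: Optional[float] = None,
                     baseline_len: int = 50) -> DesignSummary:
    """Summarize a design; distinct oligos are counted once even when shared
    across pools (shared oligos are what make the pool compact)."""
    if unit_price < 0 or (baseline_unit_price is not None and baseline_unit_price < 0):
        raise ValueError("prices must be >= 0")
    distinct = _distinct_oligos(design)
    n = len(distinct)
    bases = sum(o.length for o in distinct)
    total = sum(res.target_length for res in _results_of(design))
    cost = n * unit_price
    baseline_n = baseline_bases = baseline_cost = pct = None
    if baseline_unit_price is not None:
        baseline_n, baseline_bases = tile_end_to_end(
            [res.target_length for res in _results_of(design)], baseline_len
        )
        baseline_cost = baseline_n * baseline_unit_price
        if baseline_cost > 0:
            pct = 100.0 * (1.0 - cost / baseline_cost)
    return DesignSummary(
        n_oligos=n,
        bases_tiled=bases,
        total_target_bases=total,
        fraction_tiled=bases / total if total else 0.0,
        cost=cost,
        baseline_n_oligos=baseline_n,
        baseline_bases=baseline_bases,
        baseline_cost=baseline_cost,
        percent_cost_reduction=pct,
    )


def predicted_fragment_lengths(tiling: TilingResult, mode: str = "complete") -> List[int]:
    """Lengths of target fragments surviving RNaseH digestion.

    ``complete`` — every duplexed base is digested, so the surviving pieces
    are exactly the untiled gaps (head and tail included). ``partial`` —
    each oligo induces a single cleavage at the center of its footprint
    (position start + len//2), so an internal fragment spans the downstream
    half of the upstream oligo, the gap, and the upstream half of the
    downstream oligo: ceil(up/2) + gap + floor(down/2); terminal fragments
    get one flank only. With default parameters (gaps <= 30, oligos 39-40)
    complete fragments are <= 30 nt and partial fragments ~70 nt, short
    enough for a >200 nt size selection to remove.
    """
    if mode not in ("complete", "partial"):
        raise ValueError("mode must be 'complete' or 'partial'")
    gaps = list(tiling.gaps)
    if mode == "complete" or not tiling.oligos:
        return gaps
    lens = [o.length for o in tiling.oligos]
    frags = []
    for k, gap in enumerate(gaps):
        up = lens[k - 1] if k > 0 else None
        down = lens[k] if k < len(lens) else None
        f = gap
        if up is not None:
            f += math.ceil(up / 2)
        if down is not None:
            f += down // 2
        frags.append(f)
    return frags


def target_molarity(mass_ng: float, length_nt: float, volume_ul: float,
                    residue_mass_g_per_mol: float = 320.5) -> float:
    """Concentration (nM) of ``mass_ng`` of a ``length_nt`` single-stranded
    RNA in ``volume_ul``, using an average residue mass of 320.5 g/mol."""
    for name, v in [("mass_ng", mass_ng), ("length_nt", length_nt),
                    ("volume_ul", volume_ul), ("residue_mass_g_per_mol", residue_mass_g_per_mol)]:
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return mass_ng * 1e6 / (length_nt * residue_mass_g_per_mol * volume_ul)


_BASES = np.array(list("ACGU"))


def make_synthetic_target(length: int, gc: float = 0.5, seed: int = 0) -> TargetSeq:
    """Random RNA target of the requested length and expected GC content.

    Pure function of ``(length, gc, seed)``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return TargetSeq(id=f"synthetic_L{length}_s{seed}", seq=seq)


def make_divergent_pair(length: int, identity: float = 0.86, seed: int = 0,
                        gc: float = 0.5) -> Alignment:
    """A pair of variant sequences differing by substitutions only.

    Exactly ``round((1 - identity) * length)`` positions are substituted at
    uniformly chosen sites (realized identity within +-1% of the request for
    any length >= 50). No indels, so the pair is returned pre-aligned with
    identity column maps. Pure function of ``(length, identity, seed, gc)``.
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError("identity must be in [0, 1]")
    base = make_synthetic_target(length, gc=gc, seed=seed)
    rng = np.random.default_rng(seed + 1_000_003)
    n_sub = round((1.0 - identity) * length)
    variant = list(base.seq)
    if n_sub:
        for pos in rng.choice(length, size=n_sub, replace=False):
            others = [b for b in "ACGU" if b != variant[pos]]
            variant[pos] = others[rng.integers(len(others))]
    return Alignment(
        ids=[f"variantA_L{length}_s{seed}", f"variantB_L{length}_s{seed}"],
        rows=[base.seq, "".join(variant)],
    )
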