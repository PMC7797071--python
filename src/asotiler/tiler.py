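"""Greedy maximum-gap oligo tiling of a single target RNA.

Antisense oligos are placed left to right: each oligo is put the maximum
distance from the previous one that still satisfies the length, melting
temperature and maximum-untiled-gap constraints, so that after RNaseH
digestion every untiled fragment is short enough to be removed by size
selection. When no candidate in the current window has an in-range Tm, the
candidate whose Tm is closest to the ideal range is retained and flagged.
Near the 3' end the allowed gap is adjusted so the remaining sequence can
still be covered without any untiled run exceeding the maximum. A second
refinement phase then re-centers each oligo between its neighbors,
maximizing its smaller flanking gap without leaving the ideal Tm range.

Defaults are the designer's standard conditions: Tm 70-80 degC, oligo
length 39-40 nt, maximum untiled region 30 nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .seqio import reverse_complement
from .thermo import ThermoConfig, melting_temperature

__all__ = [
    "TilingError",
    "TargetSeq",
    "TilingParams",
    "Oligo",
    "TilingResult",
    "enumerate_candidates",
    "effective_max_gap",
    "greedy_tile",
    "refine_tiling",
    "tile_end_to_end",
]

# Degenerate (IUPAC) codes admissible in consensus sequences. N is *not*
# treated as a wildcard: in a plain target it means "unknown base" and always
# blocks candidates; a 4-fold degenerate consensus column is written as N and
# blocks likewise. '-' is the consensus mask (columns with an alignment gap).
WILDCARD_SETS: Dict[str, str] = {
    "R": "AG",
    "Y": "CU",
    "S": "CG",
    "W": "AU",
    "K": "GU",
    "M": "AC",
    "B": "CGU",
    "D": "AGU",
    "H": "ACU",
    "V": "ACG",
}
_PLAIN = set("ACGU")
_BLOCKED = {"N", "-"}
_TARGET_ALPHABET = _PLAIN | _BLOCKED | set(WILDCARD_SETS)


class TilingError(ValueError):
    """Invalid tiling input or parameters."""


@dataclass
class TargetSeq:
    """One target RNA: identifier plus sense-strand sequence (5'->3').

    The sequence is normalized to uppercase RNA (T->U). Plain targets are
    ACGU plus N; consensus sequences may additionally contain IUPAC wildcard
    codes and the '-' mask.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise TilingError("target id must be non-empty")
        s = self.seq.upper().replace("T", "U")
        for i, c in enumerate(s):
            if c not in _TARGET_ALPHABET:
                raise TilingError(
                    f"target {self.id!r}: invalid character {self.seq[i]!r} at position {i + 1}"
                )
        self.seq = s

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TilingParams:
    """User-facing design constraints.

    tm_min/tm_max in degC, len_min/len_max and max_gap in nt; max_expansion
    caps how many unambiguous oligos a retained wildcard oligo may expand to.
    """

    tm_min: float = 70.0
    tm_max: float = 80.0
    len_min: int = 39
    len_max: int = 40
    max_gap: int = 30
    max_expansion: int = 2

    def __post_init__(self) -> None:
        if self.len_min > self.len_max or self.len_min < 2:
            raise TilingError("require 2 <= len_min <= len_max")
        if not self.tm_min < self.tm_max:
            raise TilingError("require tm_min < tm_max")
        if self.max_gap < 0:
            raise TilingError("require max_gap >= 0")
        if self.max_expansion < 1:
            raise TilingError("require max_expansion >= 1")

    @property
    def tm_mid(self) -> float:
        return 0.5 * (self.tm_min + self.tm_max)


@dataclass
class Oligo:
    """A placed antisense oligo.

    ``start``/``end`` are 0-based half-open coordinates on the target;
    ``antisense_seq`` is DNA 5'->3', the reverse complement of the target
    subsequence (IUPAC codes only for wildcard oligos). ``tm`` is the
    predicted hybrid Tm in degC (for a wildcard oligo, the minimum over its
    expansions — a conservative hybridization guarantee).
    """

    id: str
    target_id: str
    start: int
    end: int
    antisense_seq: str
    tm: float
    tm_in_range: bool
    oligo_class: str = "individual"
    n_expansions: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


def oligo_name(target_id: str, start: int, length: int, wildcard: bool = False) -> str:
    """Deterministic oligo id: ``<target>_<start_1based>_<length>`` (+``_wc``)."""
    return f"{target_id}_{start + 1}_{length}" + ("_wc" if wildcard else "")


@dataclass
class TilingResult:
    """Oligos placed on one target, plus the untiled gap structure.

    ``gaps`` lists every untiled run in order, including the 5' head and the
    3' tail (``len(gaps) == len(oligos) + 1`` whenever any oligo is placed).
    """

    target: TargetSeq
    oligos: List[Oligo]
    gaps: List[int]
    bases_tiled: int
    flags: List[str] = field(default_factory=list)

    @property
    def target_id(self) -> str:
        return self.target.id

    @property
    def target_length(self) -> int:
        return self.target.length

    @classmethod
    def build(cls, target: TargetSeq, oligos: Sequence[Oligo], params: TilingParams,
              extra_flags: Sequence[str] = ()) -> "TilingResult":
        """Assemble a result, recomputing gaps, bases and structural flags."""
        oligos = sorted(oligos, key=lambda o: o.start)
        for a, b in zip(oligos, oligos[1:]):
            if b.start < a.end:
                raise TilingError(f"overlapping oligos {a.id} and {b.id}")
        if oligos:
            gaps = [oligos[0].start]
            gaps += [b.start - a.end for a, b in zip(oligos, oligos[1:])]
            gaps.append(target.length - oligos[-1].end)
        else:
            gaps = [target.length]
        flags = list(extra_flags)
        for g in gaps:
            if g > params.max_gap:
                flags.append(f"oversized_gap:{g}")
        for o in oligos:
            if not o.tm_in_range:
                flags.append(f"tm_out_of_range:{o.id}:{o.tm:.2f}")
        return cls(
            target=target,
            oligos=list(oligos),
            gaps=gaps,
            bases_tiled=sum(o.length for o in oligos),
            flags=flags,
        )


# ---------------------------------------------------------------------------
# candidate enumeration

def _window_expansions(sub: str) -> Optional[int]:
    """Degeneracy of a target window, or None if it is blocked (N or mask)."""
    n = 1
    for c in sub:
        if c in _PLAIN:
            continue
        if c in _BLOCKED:
            return None
        n *= len(WILDCARD_SETS[c])
    return n


def _window_tm(sub: str, n_exp: int, cfg: ThermoConfig) -> float:
    if n_exp == 1 and all(c in _PLAIN for c in sub):
        return melting_temperature(sub, cfg)
    from .multitarget import expand_wildcards  # deferred: avoids an import cycle

    return min(melting_temperature(e, cfg) for e in expand_wildcards(sub))


def _candidates_at(target: TargetSeq, start: int, params: TilingParams,
                   cfg: ThermoConfig) -> List[Oligo]:
    out: List[Oligo] = []
    for length in range(params.len_min, params.len_max + 1):
        end = start + length
        if end > target.length:
            continue
        sub = target.seq[start:end]
        n_exp = _window_expansions(sub)
        if n_exp is None or n_exp > params.max_expansion:
            continue
        tm = _window_tm(sub, n_exp, cfg)
        wildcard = n_exp > 1
        out.append(
            Oligo(
                id=oligo_name(target.id, start, length, wildcard),
                target_id=target.id,
                start=start,
                end=end,
                antisense_seq=reverse_complement(sub, "DNA"),
                tm=tm,
                tm_in_range=params.tm_min <= tm <= params.tm_max,
                oligo_class="wildcard" if wildcard else "individual",
                n_expansions=n_exp,
            )
        )
    return out


def enumerate_candidates(target: TargetSeq, window_start: int, window_end: int,
                         params: TilingParams, cfg: ThermoConfig) -> List[Oligo]:
    """All admissible oligos with start in ``[window_start, window_end]`` (inclusive).

    A candidate must fit on the target, stay within the length range, avoid
    N/masked positions, and (if it covers degenerate consensus positions)
    expand to at most ``params.max_expansion`` unambiguous oligos. Each is
    annotated with its Tm and whether that Tm is in range.
    """
    if not (0 <= window_start <= target.length and window_start <= window_end + 1):
        raise TilingError("candidate window out of bounds")
    cands: List[Oligo] = []
    for start in range(window_start, min(window_end, target.length) + 1):
        cands.extend(_candidates_at(target, start, params, cfg))
    return cands


# ---------------------------------------------------------------------------
# terminal gap adjustment

_feasible_cache: Dict[Tuple[int, int, int], List[bool]] = {}


def _feasible_table(params: TilingParams, upto: int) -> List[bool]:
    """feasible[r] := a remainder of r nt can be finished with no untiled run
    exceeding max_gap (oligos of length len_min..len_max, gaps >= 0)."""
    key = (params.len_min, params.len_max, params.max_gap)
    tab = _feasible_cache.setdefault(key, [])
    lens = range(params.len_min, params.len_max + 1)
    for r in range(len(tab), upto + 1):
        if r <= params.max_gap:
            tab.append(True)
        elif r < params.len_min:
            tab.append(False)
        else:
            tab.append(
                any(
                    g + ln <= r and tab[r - g - ln]
                    for g in range(0, params.max_gap + 1)
                    for ln in lens
                )
            )
    return tab


def remainder_feasible(remaining_length: int, params: TilingParams) -> bool:
    if remaining_length < 0:
        return False
    return _feasible_table(params, remaining_length)[remaining_length]


def effective_max_gap(remaining_length: int, params: TilingParams) -> int:
    """Largest admissible gap before the next oligo, given what remains.

    Far from the 3' end this is simply ``max_gap``; near the end it shrinks
    so that the remaining sequence can still be finished without any untiled
    run longer than ``max_gap`` (the greedy rule stays maximal at every
    step). For a remainder no longer than ``max_gap`` the whole remainder is
    the (compliant) tail. Total function: remainders that cannot be tiled at
    all (e.g. ``max_gap < remaining < len_min``) return ``max_gap`` and are
    flagged by the caller.
    """
    r = remaining_length
    if r < 0:
        raise TilingError("remaining_length must be >= 0")
    if r <= params.max_gap:
        return r
    if r < params.len_min:
        return params.max_gap
    tab = _feasible_table(params, r)
    lens = range(params.len_min, params.len_max + 1)
    for g in range(min(params.max_gap, r - params.len_min), -1, -1):
        if any(g + ln <= r and tab[r - g - ln] for ln in lens):
            return g
    return 0


# ---------------------------------------------------------------------------
# greedy placement

def _fallback_distance(o: Oligo, params: TilingParams) -> float:
    """Distance of an oligo's Tm to the ideal range (0 inside the range)."""
    if params.tm_min <= o.tm <= params.tm_max:
        return 0.0
    return min(abs(o.tm - params.tm_min), abs(o.tm - params.tm_max))


def _pick_in_range(cands: List[Oligo], params: TilingParams) -> Oligo:
    # largest start; then Tm closest to the range midpoint; then longer;
    # then lexicographically smaller antisense sequence (defensive, unreachable)
    return min(
        cands,
        key=lambda c: (-c.start, abs(c.tm - params.tm_mid), -c.length, c.antisense_seq),
    )


def _pick_fallback(cands: List[Oligo], params: TilingParams) -> Oligo:
    # closest Tm to the ideal range; then larger start; then longer
    return min(
        cands,
        key=lambda c: (_fallback_distance(c, params), -c.start, -c.length, c.antisense_seq),
    )


def greedy_tile(target: TargetSeq, params: TilingParams | None = None,
                cfg: ThermoConfig | None = None) -> TilingResult:
    """Place oligos left to right, each at the maximum admissible distance
    from the previous one (the 5' end acts as a virtual previous oligo ending
    at coordinate 0, so the head gap obeys the same bound)."""
    params = params or TilingParams()
    cfg = cfg or ThermoConfig()
    L = target.length
    if L < params.len_min:
        return TilingResult.build(target, [], params,
                                  extra_flags=[f"target_shorter_than_len_min:{L}"])
    oligos: List[Oligo] = []
    extra_flags: List[str] = []
    cursor = 0
    while True:
        remaining = L - cursor
        if remaining <= params.max_gap:
            break
        if remaining < params.len_min:
            break  # oversized tail; build() will flag it
        g_eff = effective_max_gap(remaining, params)
        cands = enumerate_candidates(target, cursor, cursor + g_eff, params, cfg)
        if not cands:
            # window blocked (N run / over-degenerate consensus): scan forward
            # to the next placeable start; the oversized gap is flagged.
            found = None
            for s in range(cursor + g_eff + 1, L - params.len_min + 1):
                cs = _candidates_at(target, s, params, cfg)
                if cs:
                    found = cs
                    break
            if found is None:
                break  # nothing placeable ahead; tail flagged by build()
            cands = found
        else:
            feas = [c for c in cands if remainder_feasible(L - c.end, params)]
            if feas:
                cands = feas
        in_range = [c for c in cands if c.tm_in_range]
        best = _pick_in_range(in_range, params) if in_range else _pick_fallback(cands, params)
        oligos.append(best)
        cursor = best.end
    return TilingResult.build(target, oligos, params, extra_flags=extra_flags)


# ---------------------------------------------------------------------------
# refinement

def _refine_key(up: int, down: int, o: Oligo, params: TilingParams) -> tuple:
    # maximize: smaller flanking gap; then balance; then Tm near midpoint;
    # then longer oligo; then smaller start (all deterministic)
    return (min(up, down), -abs(up - down), -abs(o.tm - params.tm_mid), o.length, -o.start)


def refine_tiling(result: TilingResult, params: TilingParams | None = None,
                  cfg: ThermoConfig | None = None) -> TilingResult:
    """Re-center each oligo within the span bounded by its neighbors.

    Repeated left-to-right passes (to a fixpoint, capped at 5) move or
    resize each oligo to maximize its smaller flanking gap. An oligo whose
    Tm is in range only moves to in-range positions; an out-of-range oligo
    never moves further from the range. No move may enlarge a flanking gap
    beyond ``max_gap`` (beyond its current size, for already-flagged gaps),
    so the gap bound survives refinement. Oligo count is unchanged.
    """
    params = params or TilingParams()
    cfg = cfg or ThermoConfig()
    target = result.target
    oligos = sorted(result.oligos, key=lambda o: o.start)
    L = target.length

    def flank_gaps(i: int) -> Tuple[int, int]:
        lo = oligos[i - 1].end if i > 0 else 0
        hi = oligos[i + 1].start if i + 1 < len(oligos) else L
        return oligos[i].start - lo, hi - oligos[i].end

    # every oligo's smaller flanking gap must end >= its pre-refinement value;
    # a move of oligo i also narrows a neighbor's shared gap, so moves are
    # admitted only while they keep both shared gaps above the neighbors'
    # original minima (inductively preserving the global guarantee)
    orig_min = [min(*flank_gaps(i)) for i in range(len(oligos))]

    for _ in range(5):
        changed = False
        for i, cur in enumerate(oligos):
            lo = oligos[i - 1].end if i > 0 else 0
            hi = oligos[i + 1].start if i + 1 < len(oligos) else L
            if hi - lo < params.len_min:
                continue
            cur_up, cur_down = cur.start - lo, hi - cur.end
            up_cap = max(params.max_gap, cur_up)
            down_cap = max(params.max_gap, cur_down)
            up_floor = orig_min[i - 1] if i > 0 else 0
            down_floor = orig_min[i + 1] if i + 1 < len(oligos) else 0
            cands = [
                c
                for c in enumerate_candidates(target, lo, hi - params.len_min, params, cfg)
                if c.end <= hi
                and up_floor <= c.start - lo <= up_cap
                and down_floor <= hi - c.end <= down_cap
            ]
            if cur.tm_in_range:
                cands = [c for c in cands if c.tm_in_range]
            else:
                d0 = _fallback_distance(cur, params)
                cands = [c for c in cands if _fallback_distance(c, params) <= d0]
            best_key = _refine_key(cur_up, cur_down, cur, params)
            best = None
            for c in cands:
                k = _refine_key(c.start - lo, hi - c.end, c, params)
                if k > best_key:
                    best_key, best = k, c
            if best is not None:
                oligos[i] = best
                changed = True
        if not changed:
            break
    return TilingResult.build(target, oligos, params)


# ---------------------------------------------------------------------------
# end-to-end baseline

def tile_end_to_end(target_lengths: Sequence[int], oligo_len: int = 50) -> Tuple[int, int]:
    """Oligo and base counts for the conventional gap-free strategy.

    Each target of length L takes ``ceil(L / oligo_len)`` oligos of
    ``oligo_len`` nt (the final oligo may overlap its predecessor to end
    flush), covering all L bases. Returns totals ``(n_oligos, bases)``.
    """
    if any(L < 1 for L in target_lengths):
        raise TilingError("target lengths must be >= 1")
    n = sum(math.ceil(L / oligo_len) for L in target_lengths)
    return n, int(sum(target_lengths))
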