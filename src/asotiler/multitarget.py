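"""Compact oligo pools shared across divergent target variants.

Two modes, mirroring how a designer targets e.g. maternal and somatic rRNA
variants with one reagent set:

* **unaligned** — the first target is tiled normally; for each further
  target, oligos with an exact complementary match are reused, and only the
  remaining untiled regions receive new oligos.
* **aligned** — a consensus of a gapped alignment is tiled first. Identical
  columns keep their base; mismatch columns become IUPAC wildcard codes; any
  column containing a gap is masked and never covered. A wildcard-bearing
  consensus oligo is retained only if it expands to at most
  ``max_expansion`` unambiguous oligos (such oligos are ordered as small
  mixtures). Residual regions of each variant are then tiled individually.

Oligos are classified ``common`` (identical in every variant), ``wildcard``
(degenerate, covering every variant via its expansions) or ``unique`` (one
variant only), so each pool's size is common + wildcard + its own uniques.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .seqio import reverse_complement
from .thermo import ThermoConfig
from .tiler import (
    Oligo,
    TargetSeq,
    TilingError,
    TilingParams,
    TilingResult,
    WILDCARD_SETS,
    greedy_tile,
    oligo_name,
    refine_tiling,
)

__all__ = [
    "MultiTargetError",
    "Alignment",
    "Consensus",
    "SharedDesign",
    "expand_wildcards",
    "build_consensus",
    "find_exact_reuse",
    "shared_tile_unaligned",
    "shared_tile_aligned",
    "classify_oligos",
    "MASK",
]

MASK = "-"

_RNA_SETS: Dict[str, str] = {"A": "A", "C": "C", "G": "G", "U": "U", "N": "ACGU"}
_RNA_SETS.update(WILDCARD_SETS)
_CODE_FOR_SET: Dict[frozenset, str] = {frozenset(v): k for k, v in _RNA_SETS.items()}


class MultiTargetError(ValueError):
    """Invalid multi-target input."""


def expand_wildcards(seq: str) -> List[str]:
    """Full Cartesian expansion of an IUPAC string, lexicographically sorted.

    Works for DNA or RNA spellings; the output uses the input's alphabet
    (T stays T, U stays U).
    """
    s = seq.upper()
    is_dna = "T" in s or ("U" not in s)
    per_pos: List[str] = []
    for i, c in enumerate(s):
        key = "U" if c == "T" else c
        if key not in _RNA_SETS:
            raise MultiTargetError(f"invalid IUPAC character {seq[i]!r} at position {i + 1}")
        choices = _RNA_SETS[key]
        per_pos.append(choices.replace("U", "T") if is_dna else choices)
    return sorted("".join(p) for p in itertools.product(*per_pos))


@dataclass
class Alignment:
    """A precomputed gapped alignment of >= 2 variant sequences.

    Rows are equal-length strings over ACGU plus '-'; ``column_maps[i][col]``
    gives row i's ungapped coordinate at alignment column ``col`` (-1 at that
    row's gap columns). Alignments are validated, never computed, here.
    """

    ids: List[str]
    rows: List[str]
    column_maps: List[List[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or len(self.rows) < 2:
            raise MultiTargetError("alignment needs >= 2 rows with matching ids")
        if len(set(self.ids)) != len(self.ids):
            raise MultiTargetError("duplicate row ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise MultiTargetError(f"alignment rows have unequal lengths {sorted(lengths)}")
        rows = []
        for rid, row in zip(self.ids, self.rows):
            r = row.upper().replace("T", "U")
            for i, c in enumerate(r):
                if c not in "ACGUN-":
                    raise MultiTargetError(
                        f"alignment row {rid!r}: invalid character {row[i]!r} at column {i + 1}"
                    )
            rows.append(r)
        self.rows = rows
        self.column_maps = []
        for row in self.rows:
            cmap, k = [], 0
            for c in row:
                if c == MASK:
                    cmap.append(-1)
                else:
                    cmap.append(k)
                    k += 1
            self.column_maps.append(cmap)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def degapped(self, index: int) -> TargetSeq:
        return TargetSeq(id=self.ids[index], seq=self.rows[index].replace(MASK, ""))


@dataclass(frozen=True)
class Consensus:
    """Per-column summary of an alignment: base, wildcard code, or mask."""

    seq: str
    degeneracy: Tuple[int, ...]  # 0 at masked columns


def build_consensus(aln: Alignment, allow_wildcards: bool, max_expansion: int = 2) -> Consensus:
    """Column-wise consensus: identical columns keep the base; mismatch
    columns get the IUPAC code of exactly the observed base set (or the mask
    when wildcards are disallowed); any column containing a gap is masked."""
    if max_expansion < 1:
        raise MultiTargetError("max_expansion must be >= 1")
    out: List[str] = []
    deg: List[int] = []
    for col in range(aln.n_columns):
        bases = {row[col] for row in aln.rows}
        if MASK in bases or "N" in bases:
            out.append(MASK)
            deg.append(0)
        elif len(bases) == 1:
            out.append(next(iter(bases)))
            deg.append(1)
        elif allow_wildcards:
            out.append(_CODE_FOR_SET[frozenset(bases)])
            deg.append(len(bases))
        else:
            out.append(MASK)
            deg.append(0)
    return Consensus(seq="".join(out), degeneracy=tuple(deg))


@dataclass(frozen=True)
class ReusePlacement:
    oligo: Oligo
    start: int

    @property
    def end(self) -> int:
        return self.start + self.oligo.length


def find_exact_reuse(oligos: Sequence[Oligo], target: TargetSeq) -> List[ReusePlacement]:
    """Every locus of ``target`` exactly complementary to one of ``oligos``.

    For a wildcard oligo, a locus matching any expansion counts. All loci are
    returned (multi-locus matches can only help depletion); the caller
    resolves overlaps.
    """
    placements: List[ReusePlacement] = []
    for o in oligos:
        sense = reverse_complement(o.antisense_seq, "RNA")
        for pattern in expand_wildcards(sense):
            pos = target.seq.find(pattern)
            while pos != -1:
                placements.append(ReusePlacement(oligo=o, start=pos))
                pos = target.seq.find(pattern, pos + 1)
    placements.sort(key=lambda p: (p.start, p.oligo.id))
    return placements


@dataclass
class SharedDesign:
    """Per-target tilings plus the cross-target oligo classification."""

    per_target: Dict[str, TilingResult]
    pool_manifests: Dict[str, List[str]]

    @property
    def class_counts(self) -> Dict:
        return classify_oligos(self)

    @property
    def total_distinct_oligos(self) -> int:
        ids = set()
        for res in self.per_target.values():
            ids.update(o.id for o in res.oligos)
        return len(ids)


def classify_oligos(design: SharedDesign) -> Dict:
    """Counts of common / wildcard / per-pool unique oligos, with the pool
    arithmetic verified: pool size == common + wildcard + that pool's uniques."""
    common_ids, wildcard_ids = set(), set()
    unique: Dict[str, int] = {}
    for pool, res in design.per_target.items():
        n_unique = 0
        for o in res.oligos:
            if o.oligo_class == "common":
                common_ids.add(o.id)
            elif o.oligo_class == "wildcard":
                wildcard_ids.add(o.id)
            else:
                n_unique += 1
        unique[pool] = n_unique
    counts = {
        "common": len(common_ids),
        "wildcard": len(wildcard_ids),
        "unique": unique,
        "total_distinct": design.total_distinct_oligos,
    }
    for pool, res in design.per_target.items():
        manifest = design.pool_manifests[pool]
        if len(manifest) != len(res.oligos):
            raise MultiTargetError(f"pool {pool!r}: manifest inconsistent with tiling")
        n_shared = sum(1 for o in res.oligos if o.oligo_class in ("common", "wildcard"))
        if n_shared + unique[pool] != len(manifest):
            raise MultiTargetError(f"pool {pool!r}: class counts do not sum to pool size")
    return counts


def _retile_residuals(target: TargetSeq, placed: List[Oligo], params: TilingParams,
                      cfg: ThermoConfig) -> Tuple[List[Oligo], List[str]]:
    """Tile every untiled interval longer than max_gap, returning new
    (class 'unique') oligos in target coordinates plus propagated flags."""
    new: List[Oligo] = []
    flags: List[str] = []
    bounds = [(o.start, o.end) for o in sorted(placed, key=lambda o: o.start)]
    edges = [0] + [e for _, e in bounds]
    starts = [s for s, _ in bounds] + [target.length]
    for a, b in zip(edges, starts):
        if b - a <= params.max_gap:
            continue
        sub = TargetSeq(id=target.id, seq=target.seq[a:b])
        res = refine_tiling(greedy_tile(sub, params, cfg), params, cfg)
        for o in res.oligos:
            new.append(
                replace(
                    o,
                    id=oligo_name(target.id, o.start + a, o.length, o.n_expansions > 1),
                    start=o.start + a,
                    end=o.end + a,
                    oligo_class="unique",
                )
            )
        flags.extend(f"residual[{a}:{b}]:{f}" for f in res.flags)
    return new, flags


def shared_tile_unaligned(targets: Sequence[TargetSeq], params: TilingParams | None = None,
                          cfg: ThermoConfig | None = None) -> SharedDesign:
    """Shared pool over unaligned targets by exact oligo reuse.

    The first target is tiled (greedy + refinement). For each subsequent
    target, first-set oligos with exact complementary matches are placed at
    every non-overlapping matched locus, and the remaining untiled regions
    are tiled fresh. First-set oligos reused in *all* other targets are
    classified ``common``; everything else is ``unique`` to its target.
    """
    params = params or TilingParams()
    cfg = cfg or ThermoConfig()
    if len(targets) < 2:
        raise MultiTargetError(
            "shared design needs >= 2 targets; use the single-target tiler otherwise"
        )
    if len({t.id for t in targets}) != len(targets):
        raise MultiTargetError("duplicate target ids")

    first = refine_tiling(greedy_tile(targets[0], params, cfg), params, cfg)
    per_target: Dict[str, TilingResult] = {}
    reused_in: Dict[str, set] = {}

    followers: Dict[str, Tuple[TargetSeq, List[Oligo], List[str]]] = {}
    for t in targets[1:]:
        placed: List[Oligo] = []
        last_end = 0
        for p in find_exact_reuse(first.oligos, t):
            if p.start < last_end:
                continue
            placed.append(
                replace(p.oligo, target_id=t.id, start=p.start, end=p.end)
            )
            last_end = p.end
            reused_in.setdefault(p.oligo.id, set()).add(t.id)
        fresh, flags = _retile_residuals(t, placed, params, cfg)
        followers[t.id] = (t, placed + fresh, flags)

    other_ids = {t.id for t in targets[1:]}
    common_ids = {oid for oid, seen in reused_in.items() if seen == other_ids}

    first_oligos = [
        replace(o, oligo_class="common" if o.id in common_ids else "unique")
        for o in first.oligos
    ]
    per_target[targets[0].id] = TilingResult.build(targets[0], first_oligos, params)
    for tid, (t, oligos, flags) in followers.items():
        final = [
            replace(o, oligo_class="common") if o.id in common_ids else o
            for o in oligos
        ]
        res = TilingResult.build(t, final, params, extra_flags=flags)
        per_target[tid] = res

    manifests = {tid: [o.id for o in res.oligos] for tid, res in per_target.items()}
    design = SharedDesign(per_target=per_target, pool_manifests=manifests)
    classify_oligos(design)  # raises on any internal inconsistency
    return design


def shared_tile_aligned(aln: Alignment, params: TilingParams | None = None,
                        cfg: ThermoConfig | None = None) -> SharedDesign:
    """Shared pool over aligned variants via a wildcard-bearing consensus.

    The consensus is tiled first (greedy + refinement); every retained
    consensus oligo maps back to ungapped coordinates in each row (masked
    columns are never spanned, so footprints are contiguous in every row).
    Degeneracy-free oligos are ``common``; degenerate ones are ``wildcard``
    with at most ``params.max_expansion`` expansions, whose Tm is reported as
    the minimum over expansions. Residual regions of each row are then tiled
    individually (``unique``).
    """
    params = params or TilingParams()
    cfg = cfg or ThermoConfig()
    consensus = build_consensus(aln, allow_wildcards=True, max_expansion=params.max_expansion)
    cons_target = TargetSeq(id="consensus", seq=consensus.seq)
    cons_res = refine_tiling(greedy_tile(cons_target, params, cfg), params, cfg)
    shared = [
        replace(o, oligo_class="wildcard" if o.n_expansions > 1 else "common")
        for o in cons_res.oligos
    ]

    per_target: Dict[str, TilingResult] = {}
    for i, rid in enumerate(aln.ids):
        row = aln.degapped(i)
        if row.length < params.len_min:
            per_target[rid] = TilingResult.build(
                row, [], params, extra_flags=[f"row_shorter_than_len_min:{row.length}"]
            )
            continue
        cmap = aln.column_maps[i]
        placed = [
            replace(
                o,
                target_id=rid,
                start=cmap[o.start],
                end=cmap[o.end - 1] + 1,
            )
            for o in shared
        ]
        fresh, flags = _retile_residuals(row, placed, params, cfg)
        per_target[rid] = TilingResult.build(row, placed + fresh, params, extra_flags=flags)

    manifests = {rid: [o.id for o in res.oligos] for rid, res in per_target.items()}
    design = SharedDesign(per_target=per_target, pool_manifests=manifests)
    classify_oligos(design)
    return design
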