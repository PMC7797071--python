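"""Shared oligo pools: consensus, wildcards, exact reuse, classification."""

import random
from itertools import product

import pytest

from asotiler import (
    Alignment,
    TargetSeq,
    TilingParams,
    build_consensus,
    classify_oligos,
    expand_wildcards,
    find_exact_reuse,
    greedy_tile,
    make_divergent_pair,
    refine_tiling,
    reverse_complement,
    shared_tile_aligned,
    shared_tile_unaligned,
)
from asotiler.multitarget import MASK, MultiTargetError, SharedDesign

from conftest import random_rna


# ---------------------------------------------------------------------------
# wildcard expansion

def test_expansion_of_plain_sequence_is_identity():
    assert expand_wildcards("ACGT") == ["ACGT"]


def test_one_r_one_y_gives_four_sequences():
    seqs = expand_wildcards("ACGRACGYAC")
    assert len(seqs) == 4
    assert seqs == sorted(seqs)
    # brute-force oracle: all combinations of A/G and C/T at the two slots
    expected = sorted(
        f"ACG{r}ACG{y}AC" for r, y in product("AG", "CT")
    )
    assert seqs == expected


def test_ryn_combinatorics():
    assert len(expand_wildcards("RYN")) == 16


def test_expansion_respects_alphabet():
    assert expand_wildcards("RU") == ["AU", "GU"]
    assert expand_wildcards("RT") == ["AT", "GT"]
    with pytest.raises(MultiTargetError, match="position 2"):
        expand_wildcards("AZ")


# ---------------------------------------------------------------------------
# consensus

def test_identical_rows_consensus_is_the_row():
    row = "ACGUACGUAC"
    cons = build_consensus(Alignment(ids=["a", "b"], rows=[row, row]), True)
    assert cons.seq == row
    assert set(cons.degeneracy) == {1}


def test_single_mismatch_column_becomes_wildcard():
    cons = build_consensus(
        Alignment(ids=["a", "b"], rows=["ACGUA", "ACGUG"]), allow_wildcards=True
    )
    assert cons.seq == "ACGUR"
    assert cons.degeneracy == (1, 1, 1, 1, 2)


def test_mismatch_masked_when_wildcards_disallowed():
    cons = build_consensus(
        Alignment(ids=["a", "b"], rows=["ACGUA", "ACGUG"]), allow_wildcards=False
    )
    assert cons.seq == "ACGU" + MASK


def test_gap_column_is_masked_and_never_tiled(cfg):
    rows = ["ACGU" * 30 + "-" + "ACGU" * 30, "ACGU" * 30 + "A" + "ACGU" * 30]
    aln = Alignment(ids=["a", "b"], rows=rows)
    cons = build_consensus(aln, True)
    assert cons.seq[120] == MASK
    design = shared_tile_aligned(aln, TilingParams(), cfg)
    for res in design.per_target.values():
        for o in res.oligos:
            if o.oligo_class in ("common", "wildcard"):
                # shared oligos come from consensus columns; none spans col 120
                pass
    # the consensus itself must never produce an oligo across the mask
    from asotiler.tiler import enumerate_candidates

    cands = enumerate_candidates(TargetSeq("c", cons.seq), 100, 140, TilingParams(), cfg)
    assert all(c.end <= 120 or c.start >= 121 for c in cands)


def test_unequal_rows_rejected():
    with pytest.raises(MultiTargetError):
        Alignment(ids=["a", "b"], rows=["ACGU", "ACG"])


def test_column_maps_bijective_on_nongap_columns():
    aln = Alignment(ids=["a", "b"], rows=["AC-GUA", "ACG-UA"])
    for row, cmap in zip(aln.rows, aln.column_maps):
        seen = [cmap[i] for i, c in enumerate(row) if c != MASK]
        assert seen == list(range(len(row.replace(MASK, ""))))
        assert all(cmap[i] == -1 for i, c in enumerate(row) if c == MASK)


# ---------------------------------------------------------------------------
# exact reuse

def test_oligo_matches_its_own_source_locus(cfg, params):
    rng = random.Random(21)
    t = TargetSeq("t", random_rna(rng, 300))
    res = greedy_tile(t, params, cfg)
    placements = find_exact_reuse(res.oligos, t)
    found = {(p.oligo.id, p.start) for p in placements}
    for o in res.oligos:
        assert (o.id, o.start) in found


def test_planted_mutation_breaks_exactly_one_oligo(cfg, params):
    rng = random.Random(22)
    t1 = TargetSeq("t1", random_rna(rng, 400))
    res = refine_tiling(greedy_tile(t1, params, cfg), params, cfg)
    assert len(res.oligos) >= 3
    victim = res.oligos[1]
    pos = (victim.start + victim.end) // 2
    base = t1.seq[pos]
    sub = next(b for b in "ACGU" if b != base)
    t2 = TargetSeq("t2", t1.seq[:pos] + sub + t1.seq[pos + 1 :])
    matched = {p.oligo.id for p in find_exact_reuse(res.oligos, t2)}
    assert victim.id not in matched
    assert matched == {o.id for o in res.oligos} - {victim.id}


def test_absent_oligo_matches_nothing(cfg, params):
    t = TargetSeq("t", "AC" * 100)
    oligo_src = greedy_tile(TargetSeq("s", "GU" * 100), params, cfg).oligos
    assert find_exact_reuse(oligo_src, t) == []


# ---------------------------------------------------------------------------
# shared designs

def test_identical_pair_unaligned_fully_reused(cfg, params):
    rng = random.Random(30)
    seq = random_rna(rng, 500, 0.25, 0.35)
    targets = [TargetSeq("a", seq), TargetSeq("b", seq)]
    design = shared_tile_unaligned(targets, params, cfg)
    counts = design.class_counts
    assert counts["wildcard"] == 0
    assert counts["unique"] == {"a": 0, "b": 0}
    assert counts["common"] == len(design.per_target["a"].oligos) > 0


def test_identical_pair_aligned_all_common(cfg, params):
    aln = make_divergent_pair(600, identity=1.0, seed=3)
    design = shared_tile_aligned(aln, params, cfg)
    counts = design.class_counts
    assert counts["wildcard"] == 0
    assert all(v == 0 for v in counts["unique"].values())
    assert counts["common"] > 0


def test_disjoint_composition_pair_shares_nothing(cfg, params):
    rng = random.Random(31)
    a = "".join(rng.choice("AC") for _ in range(300))
    b = "".join(rng.choice("GU") for _ in range(300))
    targets = [TargetSeq("a", a), TargetSeq("b", b)]
    design = shared_tile_unaligned(targets, params, cfg)
    counts = design.class_counts
    assert counts["common"] == 0
    # each target's unique count equals an independent design
    for t in targets:
        ind = refine_tiling(greedy_tile(t, params, cfg), params, cfg)
        assert counts["unique"][t.id] == len(ind.oligos)


def test_unaligned_shared_never_exceeds_independent(cfg, params):
    aln = make_divergent_pair(1500, identity=0.86, seed=5)
    targets = [aln.degapped(0), aln.degapped(1)]
    design = shared_tile_unaligned(targets, params, cfg)
    independent = sum(
        len(refine_tiling(greedy_tile(t, params, cfg), params, cfg).oligos)
        for t in targets
    )
    assert design.total_distinct_oligos <= independent


def test_aligned_shared_beats_independent_on_divergent_pair(cfg, params):
    aln = make_divergent_pair(3000, identity=0.86, seed=5)
    design = shared_tile_aligned(aln, params, cfg)
    independent = sum(
        len(refine_tiling(greedy_tile(aln.degapped(i), params, cfg), params, cfg).oligos)
        for i in (0, 1)
    )
    assert design.total_distinct_oligos < independent
    assert design.class_counts["common"] + design.class_counts["wildcard"] > 0


def brute_force_classify(design, aln):
    """Classification oracle: re-match every emitted oligo against both rows
    at its footprint and classify from the match pattern alone."""
    by_id = {}
    footprints = {}
    for i, rid in enumerate(aln.ids):
        row = aln.degapped(i).seq
        for o in design.per_target[rid].oligos:
            sense_set = set(expand_wildcards(reverse_complement(o.antisense_seq, "RNA")))
            hit = row[o.start : o.end] in sense_set
            assert hit, "every placed oligo must complement its own footprint"
            by_id.setdefault(o.id, set()).add(rid)
            footprints[o.id] = len(sense_set)
    common = wildcard = 0
    unique = dict.fromkeys(aln.ids, 0)
    for oid, rows in by_id.items():
        if len(rows) == len(aln.ids):
            if footprints[oid] == 1:
                common += 1
            else:
                wildcard += 1
        else:
            unique[next(iter(rows))] += 1
    return {"common": common, "wildcard": wildcard, "unique": unique}


def test_classification_matches_bruteforce_oracle(cfg, params):
    aln = make_divergent_pair(1200, identity=0.98, seed=9)
    design = shared_tile_aligned(aln, params, cfg)
    counts = design.class_counts
    oracle = brute_force_classify(design, aln)
    assert counts["common"] == oracle["common"]
    assert counts["wildcard"] == oracle["wildcard"]
    assert counts["unique"] == oracle["unique"]


def test_wildcard_threshold_respected(cfg):
    for max_exp in (1, 2, 4):
        p = TilingParams(max_expansion=max_exp)
        aln = make_divergent_pair(900, identity=0.95, seed=13)
        design = shared_tile_aligned(aln, p, cfg)
        for res in design.per_target.values():
            for o in res.oligos:
                assert o.n_expansions <= max_exp


def test_wildcard_oligo_expansions_cover_both_rows(cfg, params):
    aln = make_divergent_pair(1200, identity=0.97, seed=17)
    design = shared_tile_aligned(aln, params, cfg)
    saw_wildcard = False
    for i, rid in enumerate(aln.ids):
        row = aln.degapped(i).seq
        for o in design.per_target[rid].oligos:
            if o.oligo_class != "wildcard":
                continue
            saw_wildcard = True
            senses = set(expand_wildcards(reverse_complement(o.antisense_seq, "RNA")))
            assert row[o.start : o.end] in senses
    assert saw_wildcard


def test_pool_arithmetic_always_holds(cfg, params):
    for seed in (2, 11, 29):
        aln = make_divergent_pair(1000, identity=0.9, seed=seed)
        design = shared_tile_aligned(aln, params, cfg)
        counts = design.class_counts
        for pool, res in design.per_target.items():
            assert (
                counts["common"] + counts["wildcard"] + counts["unique"][pool]
                == len(design.pool_manifests[pool])
                == len(res.oligos)
            )


def test_single_target_rejected(cfg, params):
    with pytest.raises(MultiTargetError, match="single-target"):
        shared_tile_unaligned([TargetSeq("a", "ACGU" * 20)], params, cfg)


def test_inconsistent_manifest_detected(cfg, params):
    aln = make_divergent_pair(600, identity=1.0, seed=1)
    design = shared_tile_aligned(aln, params, cfg)
    design.pool_manifests[aln.ids[0]] = design.pool_manifests[aln.ids[0]][:-1]
    with pytest.raises(MultiTargetError):
        classify_oligos(design)


def test_empty_design_counts_are_zero():
    design = SharedDesign(per_target={}, pool_manifests={})
    counts = classify_oligos(design)
    assert counts["common"] == counts["wildcard"] == counts["total_distinct"] == 0
    assert counts["unique"] == {}
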