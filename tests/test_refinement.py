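"""Refinement rules: boundary cases per rule, oracle equivalences and
end-to-end planted-error recovery."""

import numpy as np
import pytest

from txrefine import (
    GeneModelSet,
    Interval,
    RefinementConfig,
    SpliceSiteKey,
    apply_junction_revisions,
    assemble_new_transcripts,
    call_coverage_islands,
    cluster_new_transcripts,
    extend_utr,
    find_new_exons,
    propose_junction_revisions,
    refine,
)
from txrefine.evidence import EvidenceBundle, is_canonical
from txrefine.refinement import CoverageIsland, apply_new_exons
from txrefine.simulate import score_recovery, simulate_evidence

from conftest import make_genome, make_junctions, make_tracks, make_transcript

CFG = RefinementConfig()


# ---------------------------------------------------------------------------
# junction revision rules
# ---------------------------------------------------------------------------

def _junction_fixture():
    """One transcript with an unsupported annotated intron [1000,1200)
    between exons of length 100, and canonical candidate splice sites
    planted at [1004,1196) and [970,1196)."""
    genome = make_genome(
        length=3000,
        plant={1004: "GTAAGT", 1190: "TTTCAG", 970: "GTCAGT"},
    )
    models = GeneModelSet(
        [make_transcript("t1", [(900, 1000), (1200, 1300)])]
    )
    return genome, models


@pytest.mark.parametrize(
    "junctions, n_expected",
    [
        # all four rules pass: 3 reads, GT-AG, contained, ratios 1.04/0.96
        ([(1004, 1196, "+", 3)], 1),
        # below two supporting tags
        ([(1004, 1196, "+", 1)], 0),
        # the previous splicing model still has tags
        ([(1000, 1200, "+", 2), (1004, 1196, "+", 3)], 0),
        # leading exon would shrink to 70% of its annotated length
        ([(970, 1196, "+", 3)], 0),
        # candidate escapes the flanking-exon window
        ([(870, 1196, "+", 3)], 0),
    ],
)
def test_junction_rules_block_exactly_their_violations(junctions, n_expected):
    genome, models = _junction_fixture()
    events = propose_junction_revisions(
        models, make_junctions(junctions), genome, CFG
    )
    assert len(events) == n_expected
    if n_expected:
        ev = events[0]
        assert (ev.old_start, ev.old_end) == (1000, 1200)
        assert (ev.new_start, ev.new_end) == (1004, 1196)
        assert ev.support_reads == 3


def test_noncanonical_candidate_rejected():
    genome = make_genome(length=3000, plant={1004: "CAAAAA", 1190: "TTTCGG"})
    models = GeneModelSet(
        [make_transcript("t1", [(900, 1000), (1200, 1300)])]
    )
    events = propose_junction_revisions(
        models, make_junctions([(1004, 1196, "+", 3)]), genome, CFG
    )
    assert events == []


def test_tie_break_prefers_more_reads_then_smaller_shift():
    genome = make_genome(
        length=3000,
        plant={1004: "GTAAGT", 1190: "TTTCAG", 1010: "GTCCGT"},
    )
    models = GeneModelSet(
        [make_transcript("t1", [(900, 1000), (1200, 1300)])]
    )
    # candidate at 1010 has more reads -> wins despite larger shift
    events = propose_junction_revisions(
        models,
        make_junctions([(1004, 1196, "+", 3), (1010, 1196, "+", 6)]),
        genome, CFG,
    )
    assert len(events) == 1 and events[0].new_start == 1010
    # equal reads -> smaller total boundary shift wins
    events = propose_junction_revisions(
        models,
        make_junctions([(1004, 1196, "+", 3), (1010, 1196, "+", 3)]),
        genome, CFG,
    )
    assert len(events) == 1 and events[0].new_start == 1004


def test_apply_junction_revision_moves_boundaries_and_reaches_fixed_point():
    genome, models = _junction_fixture()
    table = make_junctions([(1004, 1196, "+", 3)])
    events = propose_junction_revisions(models, table, genome, CFG)
    revised = apply_junction_revisions(models, events)
    t = revised["t1"]
    assert [(e.start, e.end) for e in t.exons] == [(900, 1004), (1196, 1300)]
    assert len(t.exons) == len(models["t1"].exons)
    # fixed point: re-proposing on the same evidence yields nothing
    assert propose_junction_revisions(revised, table, genome, CFG) == []
    # empty event list leaves the models identical
    same = apply_junction_revisions(models, [])
    assert same["t1"].exons == models["t1"].exons


def test_conflicting_events_on_one_intron_rejected():
    genome, models = _junction_fixture()
    events = propose_junction_revisions(
        models, make_junctions([(1004, 1196, "+", 3)]), genome, CFG
    )
    with pytest.raises(ValueError, match="conflicting"):
        apply_junction_revisions(models, events + events)


# ---------------------------------------------------------------------------
# UTR extension
# ---------------------------------------------------------------------------

def _utr_setup(depth_spec, n_samples=3, extra_transcripts=()):
    """Transcript ending at 800 on '+'; depth_spec: [(start, end, depth)]."""
    arr = np.zeros(2000)
    for s, e, d in depth_spec:
        arr[s:e] = d
    tracks = make_tracks([arr.copy() for _ in range(n_samples)])
    t = make_transcript("t1", [(500, 600), (700, 800)])
    models = GeneModelSet([t, *extra_transcripts])
    return t, tracks, models


def test_utr3_extension_walks_to_coverage_dropoff():
    t, tracks, models = _utr_setup([(500, 950, 20)])
    ev = extend_utr(t, tracks, models, CFG, side="3")
    assert ev is not None and ev.event_type == "utr3"
    assert (ev.new_start, ev.new_end) == (700, 950)
    assert "extension=150" in ev.detail


def test_utr_extension_below_100bp_not_reported():
    t, tracks, models = _utr_setup([(500, 880, 20)])
    assert extend_utr(t, tracks, models, CFG, side="3") is None


def test_utr_walk_stops_immediately_below_depth_threshold():
    t, tracks, models = _utr_setup([(500, 780, 25), (780, 800, 20),
                                    (800, 2000, 14)])
    assert extend_utr(t, tracks, models, CFG, side="3") is None


def test_utr_run_average_rule_continues_over_short_dips():
    """A 3-base dip inside otherwise-high coverage fails clause (ii) of
    the stopping rule (run-merged mean stays >= 15), so the walk continues
    to the true drop-off."""
    t, tracks, models = _utr_setup([(500, 850, 20), (853, 950, 20)])
    ev = extend_utr(t, tracks, models, CFG, side="3")
    assert ev is not None and ev.new_end == 950


def test_utr_walk_clamped_at_same_strand_neighbour():
    neighbour = make_transcript("t2", [(920, 1000), (1050, 1100)])
    t, tracks, models = _utr_setup([(500, 1500, 20)],
                                   extra_transcripts=[neighbour])
    ev = extend_utr(t, tracks, models, CFG, side="3")
    assert ev is not None and ev.new_end == 920


def test_utr_opposite_strand_gene_does_not_block():
    neighbour = make_transcript("t2", [(920, 1000), (1050, 1100)], strand="-")
    t, tracks, models = _utr_setup([(500, 950, 20)],
                                   extra_transcripts=[neighbour])
    ev = extend_utr(t, tracks, models, CFG, side="3")
    assert ev is not None and ev.new_end == 950


def test_utr5_extension_walks_left():
    arr = np.zeros(2000)
    arr[380:800] = 20
    tracks = make_tracks([arr.copy() for _ in range(3)])
    t = make_transcript("t1", [(500, 600), (700, 800)])
    ev = extend_utr(t, tracks, GeneModelSet([t]), CFG, side="5")
    assert ev is not None and ev.event_type == "utr5"
    assert (ev.new_start, ev.new_end) == (380, 600)


def test_too_few_samples_is_a_configuration_error():
    t, tracks, models = _utr_setup([(500, 950, 20)], n_samples=1)
    with pytest.raises(ValueError, match="utr_min_low_samples"):
        extend_utr(t, tracks, models, CFG, side="3")


# ---------------------------------------------------------------------------
# coverage islands
# ---------------------------------------------------------------------------

def test_islands_basic_and_length_filter():
    arr = np.zeros(1000)
    arr[500:700] = 10
    arr[800:840] = 10  # length 40 < 50
    tracks = make_tracks([arr], strand="+")
    islands = call_coverage_islands(tracks, "+", CFG)
    assert [(i.start, i.end) for i in islands] == [(500, 700)]


def _oracle_islands(pooled, min_depth, min_len):
    out, start = [], None
    for i, v in enumerate(pooled):
        if v >= min_depth and start is None:
            start = i
        elif v < min_depth and start is not None:
            if i - start >= min_len:
                out.append((start, i))
            start = None
    if start is not None and len(pooled) - start >= min_len:
        out.append((start, len(pooled)))
    return out


def test_islands_match_brute_force_oracle_on_random_tracks():
    rng = np.random.default_rng(77)
    for _ in range(20):
        arrs = [
            np.repeat(rng.integers(0, 6, 40), rng.integers(5, 40))[:800]
            for _ in range(3)
        ]
        arrs = [np.pad(a, (0, 800 - len(a)))[:800].astype(float) for a in arrs]
        tracks = make_tracks(arrs, strand="+")
        got = [
            (i.start, i.end)
            for i in call_coverage_islands(tracks, "+", CFG)
        ]
        pooled = np.sum(arrs, axis=0)
        assert got == _oracle_islands(
            pooled, CFG.island_min_depth, CFG.island_min_length
        )


# ---------------------------------------------------------------------------
# new exons
# ---------------------------------------------------------------------------

def _new_exon_fixture(junction_records, extra_transcripts=()):
    genome = make_genome(
        length=5000,
        plant={1200: "GTAAGT", 1494: "TTACAG", 1700: "GTCAGT", 1994: "TCTCAG"},
    )
    host = make_transcript("t1", [(1000, 1200), (2000, 2200)])
    models = GeneModelSet([host, *extra_transcripts])
    island = CoverageIsland(Interval("chr1", 1500, 1700, "+"), (10.0,))
    return genome, models, [island], make_junctions(junction_records)


def test_new_exon_accepted_with_both_links():
    genome, models, islands, junctions = _new_exon_fixture(
        [(1200, 1500, "+", 2), (1700, 2000, "+", 2)]
    )
    events = find_new_exons(models, islands, junctions, genome, CFG)
    assert len(events) == 1
    ev = events[0]
    assert (ev.new_start, ev.new_end) == (1500, 1700)
    assert ev.transcript_id == "t1"
    revised = apply_new_exons(models, events)
    assert len(revised["t1"].exons) == 3


def test_new_exon_rejected_when_linked_on_one_side_only():
    genome, models, islands, junctions = _new_exon_fixture(
        [(1200, 1500, "+", 2)]
    )
    assert find_new_exons(models, islands, junctions, genome, CFG) == []


def test_new_exon_rejected_when_link_below_two_reads():
    genome, models, islands, junctions = _new_exon_fixture(
        [(1200, 1500, "+", 2), (1700, 2000, "+", 1)]
    )
    assert find_new_exons(models, islands, junctions, genome, CFG) == []


def test_new_exon_rejected_at_30_percent_annotated_overlap():
    # an annotated exon of another transcript overlaps 80/200 bases (40%)
    other = make_transcript("t2", [(300, 400), (1620, 1700)])
    genome, models, islands, junctions = _new_exon_fixture(
        [(1200, 1500, "+", 2), (1700, 2000, "+", 2)],
        extra_transcripts=[other],
    )
    assert find_new_exons(models, islands, junctions, genome, CFG) == []


def test_new_exon_outside_transcript_span_rejected():
    genome, models, islands, junctions = _new_exon_fixture(
        [(1200, 1500, "+", 2), (1700, 2000, "+", 2)]
    )
    lone = CoverageIsland(Interval("chr1", 3000, 3200, "+"), (10.0,))
    assert find_new_exons(models, [lone], junctions, genome, CFG) == []


# ---------------------------------------------------------------------------
# new transcripts + clustering
# ---------------------------------------------------------------------------

def _new_transcript_fixture(extra_transcripts=(), junction_records=None):
    genome = make_genome(length=6000, plant={3200: "GTAAGT", 3394: "TTGCAG"})
    islands = [
        CoverageIsland(Interval("chr1", 3000, 3200, "+"), (10.0,)),
        CoverageIsland(Interval("chr1", 3400, 3600, "+"), (10.0,)),
    ]
    junctions = make_junctions(junction_records or [(3200, 3400, "+", 2)])
    models = GeneModelSet(list(extra_transcripts))
    return genome, models, islands, junctions


def test_two_linked_intergenic_islands_become_one_transcript():
    genome, models, islands, junctions = _new_transcript_fixture()
    events = assemble_new_transcripts(islands, junctions, models, genome, CFG)
    assert len(events) == 1
    assert events[0].exons == ((3000, 3200), (3400, 3600))


def test_single_island_is_not_a_transcript():
    genome, models, islands, junctions = _new_transcript_fixture(
        junction_records=[(4800, 4900, "+", 2)]  # unrelated junction
    )
    events = assemble_new_transcripts(
        islands[:1], junctions, models, genome, CFG
    )
    assert events == []


def test_chain_overlapping_annotated_locus_rejected():
    inside = make_transcript("t9", [(2900, 2950), (3700, 3800)])
    genome, models, islands, junctions = _new_transcript_fixture(
        extra_transcripts=[inside]
    )
    assert assemble_new_transcripts(
        islands, junctions, models, genome, CFG
    ) == []


def test_clustering_rules():
    a = make_transcript("a", [(100, 200), (300, 400)])
    b = make_transcript("b", [(50, 200), (300, 450)])  # shares junction
    c = make_transcript("c", [(120, 250)], strand="-")  # overlap, other strand
    d = make_transcript("d", [(5000, 5100)])
    clusters = cluster_new_transcripts([a, b, c, d])
    assert clusters["a"] == clusters["b"]
    assert clusters["a"] != clusters["c"]
    assert len(set(clusters.values())) == 3


def test_clustering_matches_connected_components_oracle():
    import networkx as nx

    rng = np.random.default_rng(31)
    from txrefine import introns_of

    for _ in range(15):
        ts = []
        cursor = 0
        for i in range(int(rng.integers(3, 12))):
            cursor += int(rng.integers(0, 300))
            exons = []
            pos = cursor
            for _ in range(int(rng.integers(2, 4))):
                exons.append((pos, pos + int(rng.integers(30, 100))))
                pos = exons[-1][1] + int(rng.integers(10, 100))
            ts.append(
                make_transcript(
                    f"x{i}", exons, strand=str(rng.choice(["+", "-"]))
                )
            )
        got = cluster_new_transcripts(ts)
        g = nx.Graph()
        g.add_nodes_from(t.transcript_id for t in ts)
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                a, b = ts[i], ts[j]
                if a.strand != b.strand:
                    continue
                share = set(introns_of(a)) & set(introns_of(b))
                overlap = any(
                    ea.overlap_len(eb) > 0
                    for ea in a.exons
                    for eb in b.exons
                )
                if share or overlap:
                    g.add_edge(a.transcript_id, b.transcript_id)
        want = {
            frozenset(comp) for comp in nx.connected_components(g)
        }
        by_gene = {}
        for tid, gid in got.items():
            by_gene.setdefault(gid, set()).add(tid)
        assert {frozenset(v) for v in by_gene.values()} == want


# ---------------------------------------------------------------------------
# end-to-end recovery on the synthetic benchmark
# ---------------------------------------------------------------------------

def test_planted_errors_recovered_exactly(sim, refined):
    score = score_recovery(refined.events, sim.ledger)
    assert score.n_recovered == score.n_satisfiable
    assert score.n_decoys_reported == 0
    assert score.n_off_ledger == 0
    assert score.missing == []


def test_specificity_on_truth_matched_evidence(sim):
    clean = simulate_evidence(
        sim.truth, sim.config, conservation=sim.evidence.conservation
    )
    result = refine(sim.truth, clean, sim.genome)
    assert result.events == []


def test_refinement_is_idempotent(sim, refined):
    again = refine(refined.models, sim.evidence, sim.genome)
    assert again.events == []


def test_structural_invariants_of_revisions(sim, refined):
    for ev in refined.events_of("junction"):
        assert len(refined.models[ev.transcript_id].exons) == len(
            sim.corrupted[ev.transcript_id].exons
        )
    for ev in refined.events_of("new_exon"):
        assert (
            len(refined.models[ev.transcript_id].exons)
            == len(sim.corrupted[ev.transcript_id].exons) + 1
        )
    for ev in refined.events_of("utr5", "utr3"):
        old = sim.corrupted[ev.transcript_id]
        new = refined.models[ev.transcript_id]
        assert len(new.exons) == len(old.exons)
    # every accepted (new or moved) splice boundary is canonical
    for ev in refined.events_of("junction"):
        assert is_canonical(
            sim.genome,
            SpliceSiteKey(ev.chrom, ev.new_start, ev.new_end, ev.strand),
        )
    from txrefine import introns_of

    for ev in refined.events_of("new_transcript"):
        for key in introns_of(refined.models[ev.transcript_id]):
            assert is_canonical(sim.genome, key)


def test_transcripts_affected_deduplicates(refined):
    tids = [
        e.transcript_id
        for e in refined.events
        if e.event_type != "new_transcript"
    ]
    assert refined.transcripts_affected() == len(set(tids))
    assert len(tids) > refined.transcripts_affected()  # pairs exist
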