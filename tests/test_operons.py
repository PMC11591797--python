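"""Operon inference: GFF3 parsing, criteria, oracle equivalence."""

import numpy as np
import pytest

from ppoperon.de import DERecord, DEThresholds, call_degs
from ppoperon.operons import (
    GeneFeature,
    OperonParams,
    infer_operons,
    read_gff3,
    read_operons,
    write_gff3,
    write_operons,
)
from ppoperon.pipeline import run_synthetic_study, score_recovery
from ppoperon.profiles import DistanceMatrix
from ppoperon.simulate import SimConfig

from conftest import brute_force_operons

GFF_TOY = (
    "##gff-version 3\n"
    "c1\tsrc\tgene\t1\t900\t.\t+\t.\tID=g1\n"
    "c1\tsrc\tgene\t1101\t2000\t.\t+\t.\tID=g2\n"
    "c1\tsrc\tgene\t2201\t3100\t.\t+\t.\tID=g3\n"
)


def _records(calls: dict[str, str]) -> list[DERecord]:
    """DE records with the requested calls (UP -> +2, DOWN -> -2, NS -> 0)."""
    recs = []
    for gene, call in calls.items():
        lfc = {"UP": 2.0, "DOWN": -2.0, "NS": 0.0}[call]
        p = 0.001 if call != "NS" else 0.9
        r = DERecord(gene, log2fc=lfc, pvalue=p)
        r.fdr = p
        r.call = call
        recs.append(r)
    return recs


def _identical_dm(genes: list[str]) -> DistanceMatrix:
    n = len(genes)
    return DistanceMatrix(genes, np.zeros((n, n)))


class TestReadGff3:
    def test_toy_file_in_coordinate_order(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(GFF_TOY)
        feats = read_gff3(path)
        assert [f.gene_id for f in feats] == ["g1", "g2", "g3"]
        assert feats[0].start == 1 and feats[0].end == 900
        assert feats[0].gap_to(feats[1]) == 200

    def test_crlf_accepted(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_bytes(GFF_TOY.replace("\n", "\r\n").encode())
        assert len(read_gff3(path)) == 3

    @pytest.mark.parametrize(
        "line, match",
        [
            ("c1\tsrc\tgene\t5\t900\t.\t.\t.\tID=gX", "strand"),
            ("c1\tsrc\tgene\t900\t5\t.\t+\t.\tID=gX", "coordinates"),
            ("c1\tsrc\tgene\t5\t900\t.\t+\t.\tName=gX", "ID"),
            ("c1\tsrc\tgene\t5\t900\t.\t+\t.", "columns"),
        ],
    )
    def test_located_errors(self, tmp_path, line, match):
        path = tmp_path / "g.gff3"
        path.write_text("##gff-version 3\n" + line + "\n")
        with pytest.raises(ValueError, match=match) as exc:
            read_gff3(path)
        assert "line 2" in str(exc.value)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(GFF_TOY)
        feats = read_gff3(path)
        out = tmp_path / "g2.gff3"
        write_gff3(feats, out)
        assert read_gff3(out) == feats


class TestGapSemantics:
    def test_closest_edge_gap(self):
        a = GeneFeature("a", "c", 1, 900, "+")
        b = GeneFeature("b", "c", 1101, 2000, "+")
        assert a.gap_to(b) == b.gap_to(a) == 200

    def test_overlap_is_zero_gap(self):
        a = GeneFeature("a", "c", 1, 900, "+")
        b = GeneFeature("b", "c", 850, 2000, "-")
        assert a.gap_to(b) == 0


class TestInferOperons:
    def _toy(self, strands=("+", "+", "+"), calls=("DOWN", "DOWN", "DOWN")):
        genes = ["g1", "g2", "g3"]
        feats = [
            GeneFeature("g1", "c1", 1, 900, strands[0]),
            GeneFeature("g2", "c1", 1101, 2000, strands[1]),
            GeneFeature("g3", "c1", 2201, 3100, strands[2]),
        ]
        dm = _identical_dm(genes)
        recs = _records(dict(zip(genes, calls)))
        return dm, feats, recs

    def test_all_criteria_pass_single_candidate(self):
        dm, feats, recs = self._toy()
        cands = infer_operons(dm, feats, recs)
        assert len(cands) == 1
        assert cands[0].member_genes == ["g1", "g2", "g3"]
        assert cands[0].direction == "DOWN"
        assert cands[0].max_gap_bp == 200
        assert cands[0].max_internal_distance == 0.0

    def test_middle_gene_opposite_strand_splits(self):
        # flanking genes still pair: adjacency is geometric, not ordinal
        dm, feats, recs = self._toy(strands=("+", "-", "+"))
        cands = infer_operons(dm, feats, recs)
        assert len(cands) == 1
        assert cands[0].member_genes == ["g1", "g3"]

    def test_middle_gene_ns_still_pairs_flanks(self):
        dm, feats, recs = self._toy(calls=("DOWN", "NS", "DOWN"))
        cands = infer_operons(dm, feats, recs)
        assert len(cands) == 1
        assert cands[0].member_genes == ["g1", "g3"]

    def test_discordant_directions_do_not_group(self):
        dm, feats, recs = self._toy(calls=("UP", "DOWN", "DOWN"))
        cands = infer_operons(dm, feats, recs)
        assert len(cands) == 1
        assert cands[0].member_genes == ["g2", "g3"]

    def test_window_excludes_distant_gene(self):
        genes = ["g1", "g2"]
        feats = [
            GeneFeature("g1", "c1", 1, 900, "+"),
            GeneFeature("g2", "c1", 20_000, 20_900, "+"),
        ]
        cands = infer_operons(_identical_dm(genes), feats,
                              _records({g: "DOWN" for g in genes}))
        assert cands == []

    def test_distance_cutoff_strict(self):
        genes = ["g1", "g2"]
        feats = [
            GeneFeature("g1", "c1", 1, 900, "+"),
            GeneFeature("g2", "c1", 1101, 2000, "+"),
        ]
        d = np.array([[0.0, 0.001], [0.001, 0.0]])  # exactly at cutoff
        cands = infer_operons(DistanceMatrix(genes, d), feats,
                              _records({g: "DOWN" for g in genes}))
        assert cands == []

    def test_empty_de_set_empty_result(self):
        dm, feats, _ = self._toy()
        assert infer_operons(dm, feats, []) == []

    def test_chaining_violation_split_greedily(self):
        """a-b and b-c within a loose cutoff but a-c outside it: the member
        with the largest mean internal distance is dropped."""
        genes = ["a", "b", "c"]
        feats = [
            GeneFeature("a", "c1", 1, 900, "+"),
            GeneFeature("b", "c1", 1101, 2000, "+"),
            GeneFeature("c", "c1", 2201, 3100, "+"),
        ]
        d = np.array(
            [[0.0, 0.3, 0.5],
             [0.3, 0.0, 0.3],
             [0.5, 0.3, 0.0]]
        )
        params = OperonParams(distance_cutoff=0.4)
        cands = infer_operons(DistanceMatrix(genes, d), feats,
                              _records({g: "DOWN" for g in genes}), params)
        # a and c are the extremes; one of the all-pairs-valid pairs survives
        assert len(cands) == 1
        assert cands[0].max_internal_distance < 0.4

    def test_candidate_invariants_on_synthetic_run(self):
        res = run_synthetic_study(SimConfig(rng_seed=5))
        feat = {f.gene_id: f for f in res["features"]}
        de = {r.gene_id: r for r in res["records"]}
        dm = res["distance_matrix"]
        for c in res["candidates"]:
            assert len(c.member_genes) >= 2
            assert all(feat[g].contig == c.contig for g in c.member_genes)
            assert all(feat[g].strand == c.strand for g in c.member_genes)
            assert all(de[g].call == c.direction for g in c.member_genes)
            starts = [feat[g].start for g in c.member_genes]
            assert starts == sorted(starts)
            for a, b in zip(c.member_genes, c.member_genes[1:]):
                assert feat[a].gap_to(feat[b]) <= 10_000
            for a in c.member_genes:
                for b in c.member_genes:
                    assert dm.distance(a, b) < 0.001


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [2, 9, 17])
    def test_matches_exhaustive_search(self, seed):
        """On small instances the inferred candidates equal the maximal
        valid groups found by brute-force enumeration."""
        cfg = SimConfig(n_focal_genes=60, n_planted_operons=3,
                        n_genomes=30, rng_seed=seed)
        res = run_synthetic_study(cfg)
        n_de = sum(r.call != "NS" for r in res["records"])
        assert n_de <= 25
        expected = brute_force_operons(
            res["distance_matrix"], res["features"], res["records"],
            OperonParams(),
        )
        got = {frozenset(c.member_genes) for c in res["candidates"]}
        assert got == expected


class TestRecovery:
    def test_planted_partition_recovered(self):
        res = run_synthetic_study(SimConfig(rng_seed=3))
        score = score_recovery(res["candidates"], res["truth"])
        assert score["precision"] == 1.0
        assert score["recall"] == 1.0


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [1, 4])
    def test_relaxing_parameters_never_shrinks_coverage(self, seed):
        res = run_synthetic_study(SimConfig(rng_seed=seed))
        dm, feats, recs = res["distance_matrix"], res["features"], res["records"]

        def coverage(params):
            cands = infer_operons(dm, feats, recs, params)
            return {g for c in cands for g in c.member_genes}

        base = coverage(OperonParams())
        assert base <= coverage(OperonParams(distance_cutoff=0.01))
        assert base <= coverage(OperonParams(window_bp=20_000))


class TestCandidateIO:
    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "op.tsv"
        write_operons([], path)
        assert path.read_text().strip().startswith("operon_id\t")
        assert read_operons(path) == []

    def test_round_trip(self, tmp_path):
        res = run_synthetic_study(SimConfig(rng_seed=3))
        tsv = tmp_path / "op.tsv"
        js = tmp_path / "op.json"
        write_operons(res["candidates"], tsv, js)
        back = read_operons(tsv)
        assert back == res["candidates"]
        import json

        mirrored = json.loads(js.read_text())
        assert len(mirrored) == len(res["candidates"])


def test_call_degs_feeds_inference_consistently():
    """Thresholds used for calling are the thresholds enforced in candidates."""
    recs = [DERecord("a", log2fc=0.8, pvalue=0.001),
            DERecord("b", log2fc=0.9, pvalue=0.001)]
    call_degs(recs, DEThresholds(min_abs_fc=1.5))
    feats = [GeneFeature("a", "c1", 1, 900, "+"),
             GeneFeature("b", "c1", 1101, 2000, "+")]
    cands = infer_operons(_identical_dm(["a", "b"]), feats, recs)
    assert len(cands) == 1  # both UP under the 1.5-fold threshold
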