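"""NLR classification rules, motif/ID detection, clustering, pairing."""

import itertools

import numpy as np
import pytest

from teparyscan import nlr
from teparyscan.io import DomainHit, GeneLocus, assign_ranks

import oracles


def hit(protein="p1", name="NB-ARC", acc="PF00931", evalue=1e-70, start=100,
        end=380, source="generic_pass"):
    return DomainHit(protein, name, acc, evalue, start, end, source)


def coils(protein="p1", prob=0.95, start=10, end=50):
    return DomainHit(protein, "COILS", "", 1.0 - prob, start, end, "coils")


class TestMergePasses:
    def test_profile_substitutes_generic_nbarc(self):
        generic = [hit(evalue=1e-40), hit(name="LRR_8", acc="PF13855", start=400, end=460)]
        profile = [hit(evalue=1e-80, source="profile_pass")]
        merged = nlr.merge_domain_passes(generic, profile)
        nbarc = [h for h in merged["p1"] if h.domain_name == "NB-ARC"]
        assert len(nbarc) == 1 and nbarc[0].source == "profile_pass"
        assert any(h.domain_name == "LRR_8" for h in merged["p1"])

    def test_protein_without_profile_hits_unchanged(self):
        generic = [hit(name="Pkinase", acc="PF00069")]
        merged = nlr.merge_domain_passes(generic, [])
        assert merged["p1"] == generic

    def test_profile_only_protein_gains_hit(self):
        profile = [hit(protein="p9", source="profile_pass")]
        merged = nlr.merge_domain_passes([], profile)
        assert [h.protein_id for h in merged["p9"]] == ["p9"]

    def test_non_nbarc_profile_hit_rejected(self):
        with pytest.raises(nlr.NlrError):
            nlr.merge_domain_passes([], [hit(name="TIR", acc="PF01582", source="profile_pass")])


class TestUniverse:
    def test_seed_evalue_gates_generic_pass(self):
        generic = [hit(protein="strong", evalue=1e-70), hit(protein="weak", evalue=1e-30)]
        profile = [hit(protein="rescued", source="profile_pass")]
        assert nlr.select_universe(generic, profile) == {"strong", "rescued"}


class TestArchitecture:
    def test_cnl_from_coils_nbarc_lrr(self):
        hits = [coils(), hit(start=100, end=380),
                hit(name="LRR_8", acc="PF13855", evalue=1e-10, start=420, end=480)]
        rec = nlr.classify_architecture("p1", hits)
        assert rec.arch_class == "CNL"
        assert rec.domain_string == "C-N-L"
        assert rec.is_nlr

    def test_nbarc_only_is_class_n(self):
        rec = nlr.classify_architecture("p1", [hit()])
        assert rec.arch_class == "N" and not rec.is_nlr
        assert rec.domain_string == "N"

    def test_tir_precedence_over_coils(self):
        hits = [hit(name="TIR", acc="PF01582", evalue=1e-20, start=5, end=60),
                coils(start=70, end=95), hit(start=100, end=380),
                hit(name="LRR_4", acc="PF12799", evalue=1e-8, start=400, end=460)]
        rec = nlr.classify_architecture("p1", hits)
        assert rec.arch_class == "TNL"
        assert rec.domain_string == "T-C-N-L"  # the composite reality is preserved

    def test_truth_table_over_flag_combinations(self):
        """The class is a pure function of the presence flags; enumerate all
        2^4 combinations x 1-2 NB-ARC copies against the precedence rule."""
        for t, r, c, l, n_copies in itertools.product(
            [False, True], [False, True], [False, True], [False, True], [1, 2]
        ):
            hits, pos = [], 10
            if t:
                hits.append(hit(name="TIR_2", acc="PF13676", evalue=1e-12, start=pos, end=pos + 50)); pos += 60
            if r:
                hits.append(hit(name="RPW8", acc="PF05659", evalue=1e-12, start=pos, end=pos + 50)); pos += 60
            if c:
                hits.append(coils(start=pos, end=pos + 30)); pos += 40
            for _ in range(n_copies):
                hits.append(hit(start=pos, end=pos + 280)); pos += 290
            if l:
                hits.append(hit(name="LRR_3", acc="PF07725", evalue=1e-6, start=pos, end=pos + 50))
            expected = ("T" if t else "R" if r else "C" if c else "") + "N" + ("L" if l else "")
            rec = nlr.classify_architecture("p1", hits)
            assert rec.arch_class == expected
            assert rec.is_nlr == l
            assert rec.domain_string.count("N") == n_copies

    def test_subthreshold_evidence_ignored(self):
        hits = [hit(name="TIR", acc="PF01582", evalue=2.0, start=5, end=60),
                coils(prob=0.80, start=70, end=95), hit(start=100, end=380)]
        rec = nlr.classify_architecture("p1", hits)
        assert rec.arch_class == "N"
        assert rec.domain_string == "N"

    def test_no_nbarc_rejected(self):
        with pytest.raises(nlr.NlrError):
            nlr.classify_architecture("p1", [coils()])


class TestMotifs:
    def test_substring_rule(self):
        seq = "A" * 99 + "XGTTKXXXGLPLX" + "A" * 100
        motifs = nlr.detect_motifs(seq, [hit(start=100, end=112)])
        assert motifs == {"P-loop", "ARC1"}

    def test_motif_split_across_span_boundary_absent(self):
        seq = "A" * 99 + "GT" + "TK" + "A" * 100
        motifs = nlr.detect_motifs(seq, [hit(start=90, end=101)])  # span ends inside GTTK
        assert motifs == set()

    def test_span_outside_sequence_rejected(self):
        with pytest.raises(nlr.NlrError, match="outside"):
            nlr.detect_motifs("A" * 50, [hit(start=10, end=80)])


class TestIntegratedDomains:
    def test_clear_noncanonical_is_integrated(self):
        hits = [hit(name="zf-BED", acc="PF02892", evalue=1e-5, start=10, end=50),
                hit(start=150, end=420)]
        ids = nlr.find_integrated_domains(hits)
        assert [d[0] for d in ids] == ["zf-BED"]

    def test_overlap_with_nbarc_disqualifies(self):
        hits = [hit(name="Pkinase", acc="PF00069", evalue=1e-5, start=400, end=500),
                hit(start=150, end=420)]
        assert nlr.find_integrated_domains(hits) == []

    def test_mutually_overlapping_noncanonical_pair_disqualified(self):
        hits = [hit(name="DUF1", acc="PF90001", evalue=1e-5, start=10, end=60),
                hit(name="DUF2", acc="PF90002", evalue=1e-4, start=40, end=90),
                hit(start=150, end=420)]
        assert nlr.find_integrated_domains(hits) == []

    def test_random_layouts_match_overlap_oracle(self, rng):
        canon = [("NB-ARC", True), ("TIR", True), ("LRR_8", True), ("COILS", True)]
        noncanon = [("dA", False), ("dB", False), ("dC", False)]
        for _ in range(100):
            layout, oracle_in = [], []
            for name, canonical in canon + noncanon:
                if rng.random() < 0.7:
                    start = int(rng.integers(1, 500))
                    end = start + int(rng.integers(10, 120))
                    ev = 10.0 ** -float(rng.uniform(-1, 20))
                    if canonical:
                        src = "coils" if name == "COILS" else "generic_pass"
                        acc = "" if name == "COILS" else "PF00931"
                        layout.append(DomainHit("p", name, acc, min(ev, 0.99), start, end, src))
                        oracle_in.append((name, start, end, True, min(ev, 0.99)))
                    else:
                        layout.append(DomainHit("p", name, f"PF9{name}", ev, start, end, "generic_pass"))
                        oracle_in.append((name, start, end, False, ev))
            got = sorted(d[0] for d in nlr.find_integrated_domains(layout))
            assert got == oracles.oracle_integrated(oracle_in)


def _loci(spec):
    """spec: list of (gene_id, start, end) on one chromosome."""
    return assign_ranks([GeneLocus(g, "Chr04", s, e) for g, s, e in spec])


class TestClusters:
    def test_three_genes_within_rules_form_one_cluster(self):
        # gaps 50 kb (2 intervening) and 100 kb (5 intervening)
        loci, nbarc, pos = [], [], 100_000
        for i, (gap, fillers) in enumerate([(0, 0), (50_000, 2), (100_000, 5)]):
            pos += gap
            nbarc.append((f"n{i}", pos, pos + 4000))
            pos += 4000
        spec = [(g, s, e) for g, s, e in nbarc]
        fill_positions = [(f"f{i}", nbarc[0][2] + 1000 + i * 2000, nbarc[0][2] + 2000 + i * 2000) for i in range(2)]
        fill_positions += [(f"g{i}", nbarc[1][2] + 1000 + i * 2000, nbarc[1][2] + 2000 + i * 2000) for i in range(5)]
        clusters = nlr.find_clusters({g for g, _, _ in spec}, _loci(spec + fill_positions))
        assert len(clusters) == 1
        assert clusters[0].members == ["n0", "n1", "n2"]
        assert clusters[0].cluster_id == "4A"

    def test_ten_intervening_genes_break_the_chain(self):
        spec = [("n0", 100_000, 104_000), ("n1", 160_000, 164_000), ("n2", 230_000, 234_000)]
        fillers = [(f"f{i}", 165_000 + i * 3000, 166_000 + i * 3000) for i in range(10)]
        clusters = nlr.find_clusters({"n0", "n1", "n2"}, _loci(spec + fillers))
        assert clusters == []  # only a 2-chain survives, below the minimum

    def test_distance_gap_breaks_the_chain(self):
        spec = [("n0", 100_000, 104_000), ("n1", 150_000, 154_000), ("n2", 360_000, 364_000)]
        clusters = nlr.find_clusters({"n0", "n1", "n2"}, _loci(spec))
        assert clusters == []

    def test_missing_gene_id_rejected(self):
        with pytest.raises(nlr.NlrError, match="ghost"):
            nlr.find_clusters({"ghost"}, _loci([("n0", 1, 10)]))

    def test_random_layouts_match_exhaustive_oracle(self, rng):
        for _ in range(100):
            n_nbarc = int(rng.integers(2, 13))
            n_fill = int(rng.integers(0, 40))
            starts = sorted(rng.choice(np.arange(1, 3_000_000, 2000), size=n_nbarc + n_fill, replace=False))
            ids = [f"n{i}" for i in range(n_nbarc)] + [f"f{i}" for i in range(n_fill)]
            rng.shuffle(ids)
            spec = [(gid, int(s), int(s) + 1500) for gid, s in zip(ids, starts)]
            loci = _loci(spec)
            nbarc_ids = {g for g in ids if g.startswith("n")}
            got = [c.members for c in nlr.find_clusters(nbarc_ids, loci)]
            oracle_in = [
                (g.gene_id, g.start, g.end, g.rank)
                for g in loci
                if g.gene_id in nbarc_ids
            ]
            assert got == oracles.oracle_clusters(oracle_in)


class TestRelateClusters:
    def _cluster(self, cid, members, chrom="Chr01"):
        return nlr.NbarcCluster(cid, members, chrom, (1, 2))

    def test_shared_rbh_pairs_clusters(self):
        a = [self._cluster("1A", ["gA1", "gA2", "gA3"])]
        b = [self._cluster("1A", ["gB1", "gB2", "gB3"])]
        pairings = nlr.relate_clusters(a, b, [("gA1", "gB1")])
        assert [(p.cluster_a, p.cluster_b) for p in pairings] == [("1A", "1A")]

    def test_no_shared_rbh_no_pairing(self):
        a = [self._cluster("1A", ["gA1"])]
        b = [self._cluster("1A", ["gB1"])]
        assert nlr.relate_clusters(a, b, [("gA9", "gB9")]) == []


class TestEndToEndRecovery:
    def test_planted_genome_recovered_exactly(self, nlr_sim):
        """Classification, motifs, IDs, clusters and pairings all equal the
        planted truth on the shared synthetic genome."""
        sim = nlr_sim
        for sp in (sim.species_a, sim.species_b):
            seqs = {r.id: r.seq for r in sp.proteins}
            records = nlr.classify_proteome(sp.generic_hits, sp.profile_hits, sp.coils_hits, seqs)
            assert set(records) == set(sp.truth_proteins)
            assert not any(e in records for e in sp.excluded)
            for pid, truth in sp.truth_proteins.items():
                rec = records[pid]
                assert rec.arch_class == truth["arch_class"]
                assert rec.domain_string == truth["domain_string"]
                assert sorted(rec.motifs_present) == truth["motifs"]
                assert [list(d) for d in rec.integrated_domains] == truth["integrated_domains"]
                assert rec.is_nlr == truth["is_nlr"]
            clusters = nlr.find_clusters(set(sp.truth_proteins), sp.loci)
            assert {c.cluster_id: c.members for c in clusters} == sp.truth_clusters
            # partition invariants
            all_members = [g for c in clusters for g in c.members]
            assert len(all_members) == len(set(all_members))
            assert len(all_members) <= len(sp.truth_proteins)

    def test_cross_species_pairings_recovered(self, nlr_sim):
        from teparyscan import ks as tks
        from teparyscan.io import SimilarityEdge

        sim = nlr_sim
        def edges(rows):
            out = []
            for row in rows:
                c = row.split("\t")
                out.append(SimilarityEdge(c[0], c[1], float(c[11]), float(c[10])))
            return out

        rbh = tks.reciprocal_best_hits(edges(sim.blast_ab_rows), edges(sim.blast_ba_rows))
        assert sorted(rbh) == sorted(sim.rbh_truth)
        ca = nlr.find_clusters(set(sim.species_a.truth_proteins), sim.species_a.loci)
        cb = nlr.find_clusters(set(sim.species_b.truth_proteins), sim.species_b.loci)
        pairings = nlr.relate_clusters(ca, cb, rbh)
        assert sorted((p.cluster_a, p.cluster_b) for p in pairings) == sorted(sim.pairing_truth)
        assert all(len(p.supporting_rbh_pairs) >= 1 for p in pairings)
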