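"""Novelty discovery: selection, ORF choice, clustering, expansion, MSA,
identification and the rule-based classifier."""

import random

import pytest

import venomscan as vs
from venomscan import discover, sigpep, synthdata
from venomscan.discover import (CAT_AMP, CAT_EXISTING_FAMILY,
                                CAT_NOVEL_FAMILY, CAT_NOVEL_TOXIN,
                                CAT_SECRETED, Candidate, CandidateFeatures,
                                DiscoverConfig, KnownProtein,
                                categorize_description, center_star_msa,
                                classify_cluster, cluster_candidates,
                                conserved_residue_band, expand_clusters,
                                pick_orf_with_best_signal,
                                scaffolds_compatible,
                                select_high_expressed_unidentified)
from venomscan.seqcore import Transcript

LEADER = "MKVFLLLLVISAVMVSTAHG"


def make_t(seq, tid="t", coverage=10.0, label="unidentified"):
    t = Transcript(tid, seq, 1, "telson")
    t.coverage = coverage
    t.label = label
    return t


def candidate(peptide, tid="c", coverage=50.0):
    t = make_t("ATG" + "GCC" * len(peptide), tid, coverage)
    orf = vs.Orf(tid, 1, 0, 3 * len(peptide) + 3, peptide)
    return Candidate(t, orf, sigpep.predict_signal(peptide))


class TestSelection:
    def test_threshold_and_label_guard(self):
        ts = [make_t("ACGT", "hi_unid", coverage=6.0),
              make_t("ACGT", "lo_unid", coverage=4.0),
              make_t("ACGT", "toxin", coverage=950.0, label="toxin:CaTx"),
              make_t("ACGT", "rest", coverage=40.0, label="physiological")]
        # total = 1000; 0.5% threshold = 5.0
        picked = select_high_expressed_unidentified(ts, 0.005)
        assert [t.id for t in picked] == ["hi_unid"]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            select_high_expressed_unidentified(
                [make_t("ACGT", coverage=0.0)], 0.005)


class TestPickOrf:
    def test_signal_score_dominates_length(self):
        """A short ORF with a high signal score beats a longer ORF with a
        low one, regardless of span."""
        leader_pep = LEADER + "KRDACYIAKNYCNAVYEAFCRD"
        long_pep = "M" + "DENQKR" * 14
        cds = synthdata.back_translate(
            leader_pep, __import__("numpy").random.default_rng(1))
        long_cds = synthdata.back_translate(
            long_pep, __import__("numpy").random.default_rng(2))
        # frame-shifted concatenation keeps both ORFs in separate frames
        seq = cds + "C" + long_cds
        t = make_t(seq, "t")

        def by_prefix(pep):
            score = 0.9 if pep.startswith("MKVF") else 0.2
            return sigpep.SignalPrediction(score, None, "high", True)

        orf, pred = pick_orf_with_best_signal(t, by_prefix)
        assert orf.peptide == leader_pep
        assert pred.score == 0.9

    def test_equal_scores_prefer_longer(self):
        preds = {"AAA": sigpep.SignalPrediction(0.5, None, "some", True)}

        def flat_predictor(pep):
            return sigpep.SignalPrediction(0.5, None, "some", True)

        seq = "ATGGCA" + "ATG" + "GCC" * 30 + "TAA"
        orf, _ = pick_orf_with_best_signal(make_t(seq), flat_predictor)
        assert orf.nt_start == 0  # outer (longer) ORF

    def test_no_orf_returns_none(self):
        assert pick_orf_with_best_signal(make_t("CCCCCCCCC")) is None


class TestClustering:
    def test_shared_scaffold_and_leader_link(self):
        core = "WDGYKTAF"
        a = candidate(LEADER + core + "CAAAAAAC" + "DDDD" + "CAAC", "a")
        b = candidate(LEADER + core + "CAAAAAAC" + "DDED" + "CAAC", "b",
                      coverage=40.0)
        clusters = cluster_candidates([a, b])
        assert len(clusters) == 1 and len(clusters[0].members) == 2
        assert clusters[0].seed_member.id == "a"  # higher coverage

    def test_cysteine_count_mismatch_never_links(self):
        a = candidate(LEADER + "C" * 3 + "AAAA", "a")
        b = candidate(LEADER + "C" * 8 + "AAAA", "b")
        assert len(cluster_candidates([a, b])) == 2

    def test_single_candidate_is_singlet(self):
        a = candidate(LEADER + "CAAAC", "a")
        out = cluster_candidates([a])
        assert len(out) == 1 and out[0].is_singlet
        assert out[0].id.startswith("singlet")

    def test_scaffold_gap_tolerance(self):
        assert scaffolds_compatible("CAAAC", "CAC", gap_tolerance=2)
        assert not scaffolds_compatible("CAAAAC", "CAC", gap_tolerance=2)
        assert not scaffolds_compatible("CAC", "CACAC", gap_tolerance=2)


class TestExpansion:
    def build(self):
        """A seed cluster with a real coding transcript, plus a pooled
        homologue made by swapping two codons of the seed's CDS."""
        import numpy as np

        mature = "WDGYKTAFCAAAAAACDDDDCAAC"
        seed_pep = LEADER + mature
        seed_nt = synthdata.back_translate(seed_pep,
                                           np.random.default_rng(3))
        seed_t = make_t(seed_nt, "seed", coverage=60.0)
        orf = vs.longest_orf(vs.find_orfs(seed_t))
        seed = Candidate(seed_t, orf, sigpep.predict_signal(orf.peptide))
        clusters = cluster_candidates([seed])
        # homologue: two mature-region codons replaced (D->E, A->S)
        i = 3 * (len(LEADER) + 9)
        j = 3 * (len(LEADER) + 17)
        pool_nt = (seed_nt[:i] + "TCT" + seed_nt[i + 3:j] + "GAA"
                   + seed_nt[j + 3:])
        return clusters, pool_nt

    def pooled(self, pool_nt, coverage):
        t = Transcript("pool1", pool_nt, 1, "telson")
        t.coverage = coverage
        return [t]

    def test_planted_homolog_recruited(self):
        clusters, pool_nt = self.build()
        out = expand_clusters(clusters, self.pooled(pool_nt, 40.0))
        assert out[0].member_ids == ["seed", "pool1"]

    def test_low_coverage_hit_discarded(self):
        clusters, pool_nt = self.build()
        out = expand_clusters(clusters, self.pooled(pool_nt, 3.0))
        assert out[0].member_ids == ["seed"]

    def test_no_signal_hit_discarded(self):
        clusters, pool_nt = self.build()
        pool = self.pooled(pool_nt, 40.0)

        def never(pep):
            return sigpep.SignalPrediction(0.0, None, "low", False)

        out = expand_clusters(clusters, pool, predictor=never)
        assert out[0].member_ids == ["seed"]

    def test_seed_never_removed_and_counts_nondecreasing(self, clusters):
        for cl in clusters:
            assert cl.seed_member.id in cl.member_ids
            assert len(cl.members) >= 1


class TestCenterStarMsa:
    def test_identical_sequences_gapless(self):
        msa = center_star_msa(["MKCA", "MKCA", "MKCA"])
        assert msa == ["MKCA"] * 3

    def test_two_sequences_equal_pairwise(self):
        msa = center_star_msa(["MKC", "MKAC"])
        assert sorted(msa) == ["MK-C", "MKAC"]

    def test_degap_recovers_inputs(self):
        rng = random.Random(12)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        peps = ["".join(rng.choice(aas) for _ in range(rng.randint(5, 25)))
                for _ in range(5)]
        msa = center_star_msa(peps)
        assert len({len(r) for r in msa}) == 1
        assert [r.replace("-", "") for r in msa] == peps

    def test_center_maximizes_sum_of_pairs(self):
        """On small triples the chosen center's star alignment scores at
        least as well as a star around any other sequence."""
        from venomscan import simsearch
        scheme = simsearch.ScoringScheme.protein(gap_open=10, gap_extend=1)
        rng = random.Random(20)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(6):
            peps = ["".join(rng.choice(aas)
                            for _ in range(rng.randint(3, 6)))
                    for _ in range(3)]
            star_sums = []
            for c in range(3):
                star_sums.append(sum(
                    simsearch.global_align(peps[c], peps[o], scheme).score
                    for o in range(3) if o != c))
            chosen = max(range(3), key=lambda i: (star_sums[i], -i))
            assert star_sums[chosen] == max(star_sums)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            center_star_msa(["MK"])


class TestConservedResidues:
    def test_identical_members_high(self):
        assert conserved_residue_band(["MKCA", "MKCA"]) == "high"

    def test_random_members_low(self):
        rng = random.Random(33)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        rows = ["".join(rng.choice(aas) for _ in range(30))
                for _ in range(4)]
        assert conserved_residue_band(rows) == "low"

    def test_singlet_high_by_convention(self):
        assert conserved_residue_band(["MKCA"]) == "high"

    def test_band_arithmetic(self):
        # 3 of 10 conserved columns -> f = 0.3 -> some
        rows = ["AAAWWWWWWW", "AAADDDDDDD", "AAAEEEEEEE"]
        assert conserved_residue_band(rows) == "some"


class TestIdentification:
    @pytest.mark.parametrize("desc,expected", [
        ("Potassium channel toxin alpha-KTx 4.5", "named_toxin_family_member"),
        ("Hypothetical secreted protein", "hypothetical_or_uncharacterized"),
        ("venom peptide HtC4Tx1", "named_toxin_or_venom_peptide"),
        ("Orphan peptide AbOp-11", "hypothetical_or_uncharacterized"),
        ("SH3 domain-containing protein", "no_hit"),
    ])
    def test_keyword_rules(self, desc, expected):
        assert categorize_description(desc) == expected

    def test_empty_known_set_is_no_hit(self):
        a = candidate(LEADER + "CAAAC", "a")
        cl = cluster_candidates([a])[0]
        cat, desc = discover.identify_cluster(cl, [])
        assert cat == "no_hit" and desc == ""

    def test_planted_known_match(self):
        pep = LEADER + "WDGYKTAFCAAAAAACDDDDCAAC"
        a = candidate(pep, "a")
        cl = cluster_candidates([a])[0]
        known = [KnownProtein("k1", pep, "Sodium channel toxin BmK-M1")]
        cat, desc = discover.identify_cluster(cl, known)
        assert cat == "named_toxin_family_member"
        assert "BmK-M1" in desc


class TestClassifier:
    def feats(self, **kw):
        base = dict(signal_band="high", has_conserved_c_pattern=True,
                    conserved_residue_band="high",
                    best_hit_category="hypothetical_or_uncharacterized",
                    best_hit_description="Hypothetical protein")
        base.update(kw)
        return CandidateFeatures(**base)

    def test_family_hit_wins(self):
        f = self.feats(best_hit_category="named_toxin_family_member",
                       best_hit_description="alpha-KTx toxin")
        assert classify_cluster(f) == CAT_EXISTING_FAMILY

    def test_conserved_scaffold_makes_novel_family(self):
        assert classify_cluster(self.feats()) == CAT_NOVEL_FAMILY
        assert classify_cluster(self.feats(), is_singlet=True) == \
            CAT_NOVEL_TOXIN

    def test_no_scaffold_is_secreted_protein(self):
        f = self.feats(has_conserved_c_pattern=False)
        assert classify_cluster(f) == CAT_SECRETED

    def test_antimicrobial_description_is_amp(self):
        f = self.feats(has_conserved_c_pattern=False,
                       best_hit_description="Putative antimicrobial peptide")
        assert classify_cluster(f) == CAT_AMP

    def test_incomplete_features_rejected(self):
        with pytest.raises(ValueError):
            classify_cluster(CandidateFeatures())

    def test_every_cluster_gets_one_category(self, clusters):
        cats = {CAT_EXISTING_FAMILY, CAT_NOVEL_FAMILY, CAT_NOVEL_TOXIN,
                CAT_SECRETED, CAT_AMP}
        for cl in clusters:
            assert cl.category in cats
            assert cl.features.complete()

    def test_planted_novel_families_recovered(self, clusters, dataset):
        """Each planted novel family forms one cluster with the
        novel-putative-toxin-family category."""
        truth = dataset.manifest["transcripts"]
        planted = {}
        for tid, entry in truth.items():
            if entry["true_class"].startswith("novel:"):
                planted.setdefault(entry["true_class"], set()).add(tid)
        for fam, members in planted.items():
            homes = {cl.id for cl in clusters
                     if members & set(cl.member_ids)}
            assert len(homes) == 1
            (home,) = homes
            cl = next(c for c in clusters if c.id == home)
            assert set(cl.member_ids) >= members
            assert cl.category == CAT_NOVEL_FAMILY

    def test_outputs_written(self, clusters, tmp_path):
        discover.write_cluster_table(clusters, tmp_path / "clusters.tsv")
        discover.write_cluster_msas(clusters, tmp_path / "msa")
        lines = (tmp_path / "clusters.tsv").read_text().splitlines()
        assert len(lines) == len(clusters) + 1
        for cl in clusters:
            aln = (tmp_path / "msa" / f"{cl.id}.aln.fasta").read_text()
            assert aln.count(">") == len(cl.members)
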