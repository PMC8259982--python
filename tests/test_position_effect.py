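import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tadpose.genome_model import (
    Deletion,
    GeneAnnotation,
    GenomicInterval,
    RegulatoryContact,
    TADMap,
)
from tadpose.position_effect import (
    BY_DELETION,
    BY_POSITION_EFFECT,
    NOT_CANDIDATE,
    PatientPhenotype,
    RankingParams,
    aggregate_cohort,
    disrupted_contacts,
    flanking_windows,
    percentile_rank,
    phenotype_overlap,
    predict_candidates,
    tads_disrupted,
)
from tadpose import synthetic_data as sd


def iv(start, end, chrom="chr22"):
    return GenomicInterval(chrom, start, end)


class TestFlankingWindows:
    def test_interstitial_has_both_windows(self):
        deletion = Deletion("P", iv(10_000_000, 12_000_000), terminal=False)
        windows = flanking_windows(deletion, 2_000_000)
        assert [(w.start, w.end) for w in windows] == [
            (8_000_000, 10_000_000),
            (12_000_000, 14_000_000),
        ]

    def test_terminal_deletion_has_single_proximal_window(self):
        deletion = Deletion("PMS 1", iv(42_740_931, 51_244_566), terminal=True)
        (window,) = flanking_windows(deletion)
        # ADSL starts at 40,742,504 and must fall inside this window.
        assert (window.start, window.end) == (40_740_931, 42_740_931)
        assert window.start <= 40_742_504 <= window.end

    def test_clipped_at_chromosome_origin(self):
        deletion = Deletion("P", iv(500_000, 1_000_000), terminal=False)
        windows = flanking_windows(deletion, 2_000_000)
        assert windows[0].start == 1


class TestTadsDisrupted:
    def test_breakpoint_inside_tad(self):
        tads = TADMap([iv(1, 100), iv(100, 200)])
        deletion = Deletion("P", iv(150, 180))
        assert tads_disrupted(deletion, tads) == [iv(100, 200)]

    def test_breakpoint_on_boundary_disrupts_nothing(self):
        tads = TADMap([iv(1, 100), iv(100, 200)])
        deletion = Deletion("P", iv(100, 200))
        assert tads_disrupted(deletion, tads) == []

    def test_matches_containment_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            edges = np.sort(rng.choice(np.arange(2, 1000), 5, replace=False))
            bounds = [1, *edges.tolist(), 1000]
            tads = TADMap([iv(a, b) for a, b in zip(bounds[:-1], bounds[1:])])
            s = int(rng.integers(1, 990))
            deletion = Deletion("P", iv(s, s + int(rng.integers(1, 200))))
            expected = [
                t
                for t in tads
                if t.start < deletion.interval.start < t.end
                or t.start < deletion.interval.end < t.end
            ]
            assert tads_disrupted(deletion, tads) == expected


class TestDisruptedContacts:
    def test_counts_only_overlapping_elements_of_this_gene(self):
        gene = GeneAnnotation("G1", iv(100, 200))
        deletion = Deletion("P", iv(1_000, 2_000))
        contacts = [
            RegulatoryContact("G1", iv(1_500, 1_600)),  # inside deletion
            RegulatoryContact("G1", iv(300, 400)),  # outside
            RegulatoryContact("G2", iv(1_500, 1_600)),  # other gene
        ]
        assert disrupted_contacts(gene, deletion, contacts) == 1

    def test_no_overlap_gives_zero(self):
        gene = GeneAnnotation("G1", iv(100, 200))
        deletion = Deletion("P", iv(1_000, 2_000))
        assert disrupted_contacts(gene, deletion, []) == 0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        gene = GeneAnnotation("G1", iv(100, 200))
        for _ in range(50):
            deletion = Deletion(
                "P", iv(int(rng.integers(1, 500)), int(rng.integers(500, 1000)))
            )
            contacts = [
                RegulatoryContact(
                    rng.choice(["G1", "G2"]),
                    iv(int(s := rng.integers(1, 990)), int(s + rng.integers(1, 50))),
                )
                for _ in range(10)
            ]
            expected = sum(
                1
                for c in contacts
                if c.gene_symbol == "G1"
                and len(
                    set(range(c.element.start, c.element.end))
                    & set(range(deletion.interval.start, deletion.interval.end))
                )
                > 0
            )
            assert disrupted_contacts(gene, deletion, contacts) == expected


class TestPhenotypeOverlap:
    def test_identical_sets(self):
        patient = PatientPhenotype("P", frozenset({"a", "b"}))
        gene = GeneAnnotation("G", iv(1, 2), phenotype_terms=frozenset({"a", "b"}))
        assert phenotype_overlap(patient, gene) == 1.0

    def test_disjoint_sets(self):
        patient = PatientPhenotype("P", frozenset({"a"}))
        gene = GeneAnnotation("G", iv(1, 2), phenotype_terms=frozenset({"b"}))
        assert phenotype_overlap(patient, gene) == 0.0

    def test_jaccard_half(self):
        patient = PatientPhenotype("P", frozenset({"a", "b", "c"}))
        gene = GeneAnnotation("G", iv(1, 2), phenotype_terms=frozenset({"b", "c", "d"}))
        assert phenotype_overlap(patient, gene) == 0.5

    def test_empty_gene_terms_scores_zero(self):
        patient = PatientPhenotype("P", frozenset({"a"}))
        gene = GeneAnnotation("G", iv(1, 2))
        assert phenotype_overlap(patient, gene) == 0.0

    def test_empty_patient_terms_rejected(self):
        patient = PatientPhenotype("P", frozenset())
        gene = GeneAnnotation("G", iv(1, 2))
        with pytest.raises(ValueError, match="no phenotype terms"):
            phenotype_overlap(patient, gene)


class TestPercentileRank:
    def test_single_element(self):
        assert percentile_rank([5]) == [100.0]

    def test_evenly_spaced(self):
        assert percentile_rank([1, 2, 3, 4, 5]) == [0.0, 25.0, 50.0, 75.0, 100.0]

    def test_ties_share_percentile(self):
        out = percentile_rank([1, 2, 2, 3])
        assert out[1] == out[2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank([])

    @given(st.lists(st.integers(0, 20), min_size=2, max_size=30))
    def test_matches_counting_oracle(self, scores):
        out = percentile_rank(scores)
        n = len(scores)
        for s, pct in zip(scores, out):
            below = sum(1 for v in scores if v < s)
            assert pct == pytest.approx(100.0 * below / (n - 1))


# ---------------------------------------------------------------------------
# predict_candidates against an independent rule-evaluation oracle.


def oracle_predict(deletion, genes, tad_bounds, contacts, patient_terms, params):
    """Exhaustive per-gene re-evaluation using plain tuples and arithmetic."""
    ds, de = deletion
    disrupted = [
        (a, b) for a, b in tad_bounds if a < ds < b or a < de < b
    ]
    rows = []
    for symbol, gs, ge, hi, terms in genes:
        if gs >= ds and ge <= de:
            status = "deleted"
        elif gs < de and ds < ge:
            status = "partially_deleted"
        else:
            gap = ds - ge if ge <= ds else gs - de
            status = "within_window" if gap <= params.window else "distal"
        if status == "distal":
            continue
        in_tad = any(gs < b and a < ge for a, b in disrupted)
        if status in ("deleted", "partially_deleted"):
            n_contacts = 0
        else:
            n_contacts = sum(
                1 for sym, es, ee in contacts
                if sym == symbol and es < de and ds < ee
            )
        hi_flag = hi is not None and hi <= params.hi_threshold
        union = patient_terms | terms
        overlap = len(patient_terms & terms) / len(union) if terms else 0.0
        rows.append([symbol, status, in_tad, n_contacts, hi_flag, overlap])

    n = len(rows)
    result = {}
    for row in rows:
        below = sum(1 for other in rows if other[5] < row[5])
        pct = 100.0 if n == 1 else 100.0 * below / (n - 1)
        symbol, status, in_tad, n_contacts, hi_flag, _ = row
        gate = pct > params.percentile_gate
        if status in ("deleted", "partially_deleted"):
            cls = "by_deletion" if (hi_flag or gate) else "none"
        else:
            evidence = in_tad or n_contacts > 0
            if params.combine == "and":
                is_pe = status == "within_window" and evidence
            else:
                is_pe = status == "within_window" or evidence
            cls = "by_position_effect" if is_pe else "none"
        result[symbol] = cls
    return result


def random_problem(rng, n_genes=50):
    chrom_length = 50_000_000
    locus = sd.gen_locus(
        n_genes=n_genes, chrom_length=chrom_length, seed=int(rng.integers(2**31))
    )
    size = int(rng.integers(100_000, 9_000_000))
    end = int(rng.integers(size + 1, chrom_length))
    deletion = Deletion("P", iv(end - size, end), terminal=bool(rng.integers(2)))
    terms = frozenset(
        rng.choice(sd.PHENOTYPE_VOCABULARY, size=6, replace=False).tolist()
    )
    params = RankingParams(
        window=int(rng.choice([500_000, 1_000_000, 2_000_000])),
        hi_threshold=float(rng.choice([5.0, 10.0, 20.0])),
        percentile_gate=float(rng.choice([50.0, 75.0, 90.0])),
        combine=str(rng.choice(["and", "or"])),
    )
    return locus, deletion, PatientPhenotype("P", terms), params


def as_tuples(locus):
    genes = [
        (g.symbol, g.interval.start, g.interval.end, g.hi_score,
         set(g.phenotype_terms))
        for g in locus.genes
    ]
    tads = [(t.start, t.end) for t in locus.tadmap]
    contacts = [(c.gene_symbol, c.element.start, c.element.end)
                for c in locus.contacts]
    return genes, tads, contacts


class TestPredictCandidates:
    def test_empty_annotation_gives_empty_list(self):
        deletion = Deletion("P", iv(100, 200))
        patient = PatientPhenotype("P", frozenset({"a"}))
        assert predict_candidates(deletion, [], TADMap([]), [], patient) == []

    def test_deleted_relevant_gene_is_deletion_candidate(self):
        deletion = Deletion("P", iv(1_000_000, 2_000_000))
        gene = GeneAnnotation(
            "G1", iv(1_100_000, 1_200_000), hi_score=5.0,
            phenotype_terms=frozenset({"a"}),
        )
        patient = PatientPhenotype("P", frozenset({"a"}))
        (feat,) = predict_candidates(deletion, [gene], TADMap([]), [], patient)
        assert feat.candidate_class == BY_DELETION
        assert feat.hi_flag

    def test_matches_oracle_on_random_loci(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            locus, deletion, patient, params = random_problem(rng)
            features = predict_candidates(
                deletion, locus.genes, locus.tadmap, locus.contacts,
                patient, params,
            )
            genes, tads, contacts = as_tuples(locus)
            expected = oracle_predict(
                (deletion.interval.start, deletion.interval.end),
                genes, tads, contacts, set(patient.terms), params,
            )
            got = {f.gene_symbol: f.candidate_class for f in features}
            assert got == expected

    def test_no_gene_in_both_classes_and_sorted(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            locus, deletion, patient, params = random_problem(rng)
            features = predict_candidates(
                deletion, locus.genes, locus.tadmap, locus.contacts,
                patient, params,
            )
            classes = {f.candidate_class for f in features}
            assert classes <= {BY_DELETION, BY_POSITION_EFFECT, NOT_CANDIDATE}
            scores = [f.rank_score for f in features]
            assert scores == sorted(scores, reverse=True)

    def test_shrinking_window_never_grows_position_effect_set(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            locus, deletion, patient, params = random_problem(rng)
            sets = []
            for window in (2_000_000, 1_000_000, 500_000):
                features = predict_candidates(
                    deletion, locus.genes, locus.tadmap, locus.contacts,
                    patient,
                    RankingParams(window=window, combine=params.combine),
                )
                sets.append({
                    f.gene_symbol for f in features
                    if f.candidate_class == BY_POSITION_EFFECT
                })
            assert sets[2] <= sets[1] <= sets[0]

    def test_no_tads_no_contacts_no_position_effect(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            locus, deletion, patient, _ = random_problem(rng)
            features = predict_candidates(
                deletion, locus.genes, TADMap([]), [], patient, RankingParams()
            )
            assert not any(
                f.candidate_class == BY_POSITION_EFFECT for f in features
            )

    def test_unknown_contact_symbol_warns_and_is_skipped(self):
        deletion = Deletion("P", iv(1_000_000, 2_000_000))
        gene = GeneAnnotation("G1", iv(2_100_000, 2_200_000),
                              phenotype_terms=frozenset({"a"}))
        contacts = [RegulatoryContact("GHOST", iv(1_500_000, 1_500_100))]
        patient = PatientPhenotype("P", frozenset({"a"}))
        with pytest.warns(UserWarning, match="GHOST"):
            features = predict_candidates(
                deletion, [gene], TADMap([]), contacts, patient
            )
        assert features[0].disrupted_contact_count == 0

    def test_planted_gene_ranks_top3(self):
        """A true dysregulated gene planted in a disrupted TAD with contacts
        crossing the breakpoint must surface at the top of the ranking."""
        hits = 0
        n = 200
        for seed in range(n):
            locus = sd.gen_locus(n_genes=50, seed=seed)
            cohort = sd.gen_cohort(n_patients=1, seed=seed + 10_000)
            truth, locus = sd.plant_truth(
                locus, cohort, n_position_effect=1, seed=seed + 20_000
            )
            planted = truth.planted_pairs.get(cohort[0].patient_id, ())
            if not planted:
                hits += 1  # nothing plantable in this landscape; vacuous
                continue
            phen = sd.gen_patient_phenotypes(
                cohort, locus, truth, seed=seed + 30_000
            )
            features = predict_candidates(
                cohort[0], locus.genes, locus.tadmap, locus.contacts, phen[0]
            )
            top3 = [f.gene_symbol for f in features[:3]]
            if planted[0] in top3:
                hits += 1
        assert hits / n >= 0.95


class TestAggregateCohort:
    def make_features(self, locus, deletion, patient):
        return predict_candidates(
            deletion, locus.genes, locus.tadmap, locus.contacts, patient
        )

    def test_single_patient_counts_are_binary(self):
        rng = np.random.default_rng(6)
        locus, deletion, patient, _ = random_problem(rng)
        table = aggregate_cohort([self.make_features(locus, deletion, patient)])
        assert table["n_by_deletion"].isin([0, 1]).all()
        assert table["n_by_position_effect"].isin([0, 1]).all()

    def test_duplicated_patient_doubles_counts(self):
        rng = np.random.default_rng(8)
        locus, deletion, patient, _ = random_problem(rng)
        features = self.make_features(locus, deletion, patient)
        once = aggregate_cohort([features])
        twice = aggregate_cohort([features, features])
        assert (twice["n_candidate"] == 2 * once["n_candidate"]).all()

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(9)
        per_patient = []
        for _ in range(4):
            locus, deletion, patient, _ = random_problem(rng)
            per_patient.append(self.make_features(locus, deletion, patient))
        table = aggregate_cohort(per_patient)
        for gene in table.index:
            expected = sum(
                1
                for features in per_patient
                for f in features
                if f.gene_symbol == gene and f.candidate_class == BY_DELETION
            )
            assert table.loc[gene, "n_by_deletion"] == expected

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cohort([])
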