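import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mengen.neo import (
    PeptidePair,
    best_epitope,
    call_neoantigens,
    clonal_neoantigen_contrast,
    composite_affinity,
    enumerate_peptides,
    estimate_ccf,
    expression_filter,
    pairs_from_table,
)
from mengen.simdata import SimConfig, simulate_cohort

from _oracles import best_pair_exhaustive

PROTEIN = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"


def pair(mid="m1", mut_median=100.0, wt_median=200.0, peptide="AAAAAAAA",
         allele="HLA-A*02:01", length=8):
    return PeptidePair(
        mutation_id=mid, hla_allele=allele, length=length,
        mut_peptide=peptide, wt_peptide="W" + peptide[1:],
        mut_affinities=(mut_median,), wt_affinities=(wt_median,),
    )


class TestEnumeratePeptides:
    def test_central_missense_window_count(self):
        pairs = enumerate_peptides(PROTEIN, position=60, alt_residue="W")
        assert len(pairs) == 8 + 9 + 10 + 11 + 15  # 53 pairs per allele
        for p in pairs:
            assert len(p.mut_peptide) == p.length == len(p.wt_peptide)
            assert "W" in p.mut_peptide

    def test_terminal_missense_single_window_per_length(self):
        pairs = enumerate_peptides(PROTEIN, position=1, alt_residue="W")
        by_len = {}
        for p in pairs:
            by_len.setdefault(p.length, []).append(p)
        assert {k: len(v) for k, v in by_len.items()} == {8: 1, 9: 1, 10: 1, 11: 1, 15: 1}

    def test_frameshift_matches_window_oracle(self):
        suffix = "GGGGGGGGGGGGGGGGGGGG"  # 20 novel residues
        position = 50
        pairs = enumerate_peptides(PROTEIN, position=position, novel_suffix=suffix)
        mut_seq = PROTEIN[: position - 1] + suffix
        for L in (8, 9, 10, 11, 15):
            # oracle: every in-bounds window overlapping a novel residue
            expected = {
                mut_seq[s : s + L]
                for s in range(len(mut_seq) - L + 1)
                if s + L >= position  # contains at least one novel residue
            }
            got = {p.mut_peptide for p in pairs if p.length == L}
            assert got == expected
        assert all(p.wt_peptide is None for p in pairs)

    def test_position_outside_protein_rejected(self):
        with pytest.raises(ValueError):
            enumerate_peptides(PROTEIN, position=0, alt_residue="W")
        with pytest.raises(ValueError):
            enumerate_peptides("SHORT", position=99, alt_residue="W")


class TestCompositeAffinity:
    def test_odd_count_median(self):
        assert composite_affinity([100, 200, 300, 400, 500]) == 300

    def test_even_count_mean_of_central(self):
        assert composite_affinity([50, 150]) == 100

    def test_single_predictor_identity(self):
        assert composite_affinity([42.0]) == 42.0


class TestBestEpitope:
    def test_minimum_median_wins(self):
        best = best_epitope([pair(mut_median=400.0), pair(mut_median=40.0)])
        assert best.mut_median == 40.0

    def test_tie_broken_by_ratio(self):
        a = PeptidePair("m", "h", 8, "AAAAAAAA", "CAAAAAAA", (40.0,), (400.0,))
        b = PeptidePair("m", "h", 8, "DDDDDDDD", "CDDDDDDD", (40.0,), (80.0,))
        assert best_epitope([a, b]) is a  # ratio 0.1 beats 0.5

    def test_matches_exhaustive_argmin(self, rng):
        pairs = [
            pair(mut_median=float(rng.uniform(10, 5000)),
                 wt_median=float(rng.uniform(10, 5000)),
                 peptide="".join(rng.choice(list("ACDEFGH"), 8)))
            for _ in range(100)
        ]
        assert best_epitope(pairs) is best_pair_exhaustive(pairs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_epitope([])


class TestCallNeoantigens:
    def test_cutoff_boundary(self):
        flags, burden, frac = call_neoantigens(
            {"a": [pair(mut_median=499.0)], "b": [pair(mut_median=501.0)]}
        )
        assert flags == {"a": True, "b": False}
        assert burden == 1
        assert frac == 0.5

    def test_zero_mutations_degenerate(self):
        flags, burden, frac = call_neoantigens({})
        assert flags == {} and burden == 0 and np.isnan(frac)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1, 10_000), min_size=1, max_size=20),
           st.floats(10, 5000), st.floats(10, 5000))
    def test_lower_cutoff_never_increases_burden(self, medians, cut1, cut2):
        lo, hi = sorted([cut1, cut2])
        table = {f"m{i}": [pair(mut_median=m)] for i, m in enumerate(medians)}
        _, b_lo, _ = call_neoantigens(table, binder_cutoff_nm=lo)
        _, b_hi, _ = call_neoantigens(table, binder_cutoff_nm=hi)
        assert b_lo <= b_hi

    def test_generator_binder_rate_recovered(self):
        # trunk-only cohort at a known 66% binder rate, >= 1000 mutations
        cfg = SimConfig(
            n_patients=60, samples_per_patient=1, clones_per_patient=1,
            neo_binder_rate_trunk=0.66, neo_binder_rate_subclone=0.66,
            grade_probs={"II": 1.0}, seed=55,
        )
        cohort = simulate_cohort(cfg)
        pairs = pairs_from_table(cohort.affinities)
        assert len(pairs) >= 1000
        _, _, frac = call_neoantigens(pairs)
        assert abs(frac - 0.66) <= 0.03


class TestRatio:
    def test_scale_invariance(self):
        p1 = PeptidePair("m", "h", 8, "AAAAAAAA", "CAAAAAAA",
                         (100.0, 200.0, 300.0), (50.0, 60.0, 70.0))
        c = 7.5
        p2 = PeptidePair("m", "h", 8, "AAAAAAAA", "CAAAAAAA",
                         tuple(c * v for v in p1.mut_affinities),
                         tuple(c * v for v in p1.wt_affinities))
        assert p1.ratio == pytest.approx(p2.ratio)

    def test_identical_peptides_force_unit_ratio(self):
        p = PeptidePair("m", "h", 8, "AAAAAAAA", "AAAAAAAA", (100.0,), (900.0,))
        assert p.ratio == 1.0


class TestEstimateCcf:
    def test_clonal_closed_form(self):
        est = estimate_ccf(0.5, 1.0, 2, 1)
        assert est.ccf == pytest.approx(1.0)
        assert est.clonal

    def test_subclonal_closed_form(self):
        est = estimate_ccf(0.125, 0.5, 2, 1)
        assert est.ccf == pytest.approx(0.5)
        assert not est.clonal

    def test_cap_preserves_raw_value(self):
        est = estimate_ccf(0.9, 0.8, 2, 1)
        assert est.ccf == 1.0
        assert est.uncapped_ccf > 1.0

    def test_nonpositive_purity_rejected(self):
        with pytest.raises(ValueError):
            estimate_ccf(0.3, 0.0)

    def test_recovery_error_small_at_depth_100(self, rng):
        from mengen.simdata import sample_allele_fraction
        errs = []
        for _ in range(2000):
            ccf = float(rng.uniform(0.2, 1.0))
            purity = float(rng.uniform(0.8, 1.0))
            alt, dep = sample_allele_fraction(ccf, purity, 2, 100, rng)
            errs.append(abs(estimate_ccf(alt / dep, purity, 2).ccf - ccf))
        assert np.median(errs) < 0.1


class TestClonalContrast:
    def test_all_clonal_degenerate(self):
        flags = {"a": True, "b": False}
        ccfs = {k: estimate_ccf(0.5, 1.0, mutation_id=k) for k in flags}
        f_neo, f_other, p = clonal_neoantigen_contrast(flags, ccfs)
        assert (f_neo, f_other, p) == (1.0, 1.0, 1.0)

    def test_type_one_error_under_independence(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            flags = {f"m{i}": bool(rng.random() < 0.6) for i in range(1000)}
            ccfs = {
                k: estimate_ccf(0.5 if rng.random() < 0.2 else 0.2, 1.0, mutation_id=k)
                for k in flags
            }
            _, _, p = clonal_neoantigen_contrast(flags, ccfs)
            hits += p < 0.05
        assert abs(hits / reps - 0.05) <= 0.02 + 1e-12

    def test_generator_enrichment_direction_recovered(self):
        # clonal (trunk) mutations carry a higher binder rate by construction
        cfg = SimConfig(
            n_patients=40, samples_per_patient=2, clones_per_patient=2,
            neo_binder_rate_trunk=0.8, neo_binder_rate_subclone=0.4,
            grade_probs={"II": 1.0}, seed=61,
        )
        cohort = simulate_cohort(cfg)
        truth = cohort.truth_mutations.set_index("mutation_id")
        pairs = pairs_from_table(cohort.affinities)
        flags, _, _ = call_neoantigens(pairs)
        trunk_ids = set(
            truth.index[truth.clone.str.endswith("_c1")]
        )
        ccfs = {
            mid: estimate_ccf(0.5 if mid in trunk_ids else 0.2, 1.0, mutation_id=mid)
            for mid in flags
        }
        f_neo, f_other, p = clonal_neoantigen_contrast(flags, ccfs)
        assert f_neo > f_other
        assert p < 0.05


class TestExpressionFilter:
    def test_bottom_quartile_dropped(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 4.0]}, index=["gA", "gB", "gC", "gD"]
        )
        retained, _ = expression_filter(expr, [])
        assert retained == ["gB", "gC", "gD"]

    def test_full_overlap_when_neoantigen_genes_expressed(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 4.0]}, index=["gA", "gB", "gC", "gD"]
        )
        _, overlap = expression_filter(expr, ["gC", "gD"])
        assert overlap == 1.0

    def test_ties_broken_by_gene_name_matches_sort_oracle(self, rng):
        genes = [f"g{i:02d}" for i in range(12)]
        means = rng.choice([1.0, 2.0, 3.0], size=12)  # deliberate ties
        expr = pd.DataFrame({"s1": means, "s2": means}, index=genes)
        retained, _ = expression_filter(expr, [])
        order = sorted(genes, key=lambda g: (expr.loc[g].mean(), g))
        assert retained == sorted(order[len(genes) // 4 :])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            expression_filter(pd.DataFrame(), [])


def test_neoantigen_fraction_stable_across_recurrences():
    # per-patient fraction varies little across serial samples when each
    # sample carries >= 50 mutations (coefficient of variation < 0.3)
    cfg = SimConfig(
        n_patients=12, samples_per_patient=3, clones_per_patient=3,
        mutations_per_clone=40, grade_probs={"II": 1.0}, seed=71,
    )
    cohort = simulate_cohort(cfg)
    pairs = pairs_from_table(cohort.affinities)
    flags, _, _ = call_neoantigens(pairs)
    truth = cohort.truth_mutations.set_index("mutation_id")
    ccf = cohort.truth_ccf
    cvs = []
    for pid, tree in cohort.clone_trees.items():
        fracs = []
        for m in (x for x in cohort.metas if x.patient_id == pid):
            present = set(
                ccf[(ccf.sample_id == m.sample_id) & (ccf.true_ccf > 0)].mutation_id
            )
            nonsyn = [mid for mid in present if truth.loc[mid, "nonsynonymous"]]
            if len(nonsyn) < 50:
                continue
            fracs.append(np.mean([flags.get(mid, False) for mid in nonsyn]))
        if len(fracs) >= 2:
            cvs.append(np.std(fracs, ddof=1) / np.mean(fracs))
    assert cvs, "no patients with enough mutations"
    assert float(np.mean(cvs)) < 0.3
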