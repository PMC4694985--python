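"""CNR, BTIF and PAS computations against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paslink.expression import ControlSet, ExpressionMatrix, join_case_control, \
    quantile_normalize_frame
from paslink.pas import (
    GeneStat,
    PASParams,
    compute_btif,
    compute_cnr,
    compute_pas,
    compute_pas_profile,
    read_pas_profile,
    write_pas_profile,
)
from paslink.pathway_db import GeneRole, PathwayDefinition


class TestCNR:
    def test_case_over_control_mean(self):
        assert compute_cnr(10.0, [5.0, 5.0]) == pytest.approx(2.0)

    def test_case_equal_to_mean_is_one(self):
        assert compute_cnr(4.0, [3.0, 5.0]) == pytest.approx(1.0)

    def test_random_matches_mean_and_divide_oracle(self, rng):
        for _ in range(50):
            case = rng.uniform(0.1, 100)
            ctrl = rng.uniform(0.1, 100, size=rng.integers(2, 20))
            assert compute_cnr(case, ctrl) == pytest.approx(case / (sum(ctrl) / len(ctrl)))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_cnr(-1.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            compute_cnr(1.0, [0.0, 2.0])
        with pytest.raises(ValueError):
            compute_cnr(1.0, [2.0])


class TestBTIF:
    def test_cnr_inside_band_never_flagged(self):
        # case equals the control mean: CNR = 1 lies inside [0.66, 1.5]
        ctrl = [99.9, 100.1, 100.0, 99.95, 100.05]
        btif, _ = compute_btif(np.mean(ctrl), ctrl)
        assert btif == 0

    def test_large_shift_with_tight_controls_flagged(self):
        ctrl = [100.0, 101.0, 99.0, 100.5, 99.5]
        btif, p = compute_btif(300.0, ctrl)
        assert btif == 1 and p < 0.05

    def test_zero_variance_controls_warn_and_never_flag_statistically(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            btif, p = compute_btif(300.0, [100.0, 100.0, 100.0])
        assert p == 1.0 and btif == 0

    def test_sweep_matches_two_criteria_oracle(self, rng):
        """Flags across a sweep of case values equal a brute-force oracle
        applying the tolerance-interval and fold-change criteria separately."""
        ctrl = rng.normal(100, 5, size=20)
        ctrl = np.abs(ctrl)
        mean, sd, n = ctrl.mean(), ctrl.std(ddof=1), len(ctrl)
        for case in np.linspace(40, 220, 181):
            btif, p = compute_btif(case, ctrl)
            # oracle: independent reimplementation of both criteria
            cnr_o = case / mean
            z_o = (case - mean) / (sd * np.sqrt(1 + 1 / n))
            p_o = 2 * (1 - stats.t.cdf(abs(z_o), df=n - 1))
            flag_o = int(p_o < 0.05 and (cnr_o < 0.66 or cnr_o > 1.5))
            assert btif == flag_o
            assert p == pytest.approx(p_o, rel=1e-9)

    def test_thresholds_configurable(self):
        ctrl = [100.0, 101.0, 99.0, 100.5, 99.5]
        loose, _ = compute_btif(130.0, ctrl)
        tight, _ = compute_btif(130.0, ctrl, low_thresh=0.9, high_thresh=1.1)
        assert loose == 0 and tight == 1


def _stat(gene, cnr, btif):
    return GeneStat(gene, cnr=cnr, btif=btif)


class TestPAS:
    def test_single_activator_log10(self):
        pw = PathwayDefinition("P", "signaling", [GeneRole("A", 1.0)])
        assert compute_pas(pw, {"A": _stat("A", 10.0, 1)}) == pytest.approx(1.0)

    def test_all_flags_zero_gives_zero(self):
        pw = PathwayDefinition("P", "signaling",
                               [GeneRole("A", 1.0), GeneRole("B", -1.0)])
        stats_map = {"A": _stat("A", 10.0, 0), "B": _stat("B", 0.1, 0)}
        assert compute_pas(pw, stats_map) == 0.0

    def test_activator_repressor_symmetry_cancels(self):
        pw = PathwayDefinition("P", "signaling",
                               [GeneRole("A", 1.0), GeneRole("B", -1.0)])
        stats_map = {"A": _stat("A", 100.0, 1), "B": _stat("B", 100.0, 1)}
        assert compute_pas(pw, stats_map) == pytest.approx(0.0)

    def test_random_pathway_matches_termwise_oracle(self, rng):
        from paslink.pathway_db import ARR_VALUES

        genes = [f"G{i}" for i in range(30)]
        members = [GeneRole(g, float(rng.choice(ARR_VALUES))) for g in genes]
        pw = PathwayDefinition("P", "metabolic", members)
        stats_map = {
            g: _stat(g, float(rng.uniform(0.05, 20)), int(rng.integers(0, 2)))
            for g in genes
        }
        expected = 0.0  # independent term-by-term summation
        for m in members:
            s = stats_map[m.gene_symbol]
            expected += m.arr * s.btif * np.log10(s.cnr)
        assert compute_pas(pw, stats_map) == pytest.approx(expected, rel=1e-12)

    def test_missing_genes_contribute_zero(self):
        pw = PathwayDefinition("P", "signaling",
                               [GeneRole("A", 1.0), GeneRole("Z", 1.0)])
        assert compute_pas(pw, {"A": _stat("A", 10.0, 1)}) == pytest.approx(1.0)

    def test_no_gene_present_warns_and_returns_zero(self):
        pw = PathwayDefinition("P", "signaling", [GeneRole("Z", 1.0)])
        with pytest.warns(UserWarning, match="no member gene"):
            assert compute_pas(pw, {}) == 0.0

    def test_sign_equivariance(self, rng):
        genes = [f"G{i}" for i in range(10)]
        members = [GeneRole(g, float(rng.choice([-1.0, -0.5, 0.5, 1.0]))) for g in genes]
        flipped = [GeneRole(m.gene_symbol, -m.arr) for m in members]
        stats_map = {
            g: _stat(g, float(rng.uniform(0.1, 10)), int(rng.integers(0, 2)))
            for g in genes
        }
        pas = compute_pas(PathwayDefinition("P", "signaling", members), stats_map)
        neg = compute_pas(PathwayDefinition("P", "signaling", flipped), stats_map)
        assert neg == pytest.approx(-pas, rel=1e-12)

    def test_monotone_in_flagged_activator_cnr(self):
        pw = PathwayDefinition("P", "signaling",
                               [GeneRole("A", 1.0), GeneRole("B", -0.5)])
        base = {"A": _stat("A", 2.0, 1), "B": _stat("B", 0.5, 1)}
        last = -np.inf
        for cnr in (2.0, 3.0, 5.0, 10.0, 50.0):
            stats_map = dict(base, A=_stat("A", cnr, 1))
            pas = compute_pas(pw, stats_map)
            assert pas >= last
            last = pas

    def test_member_order_irrelevant(self, rng):
        genes = [f"G{i}" for i in range(8)]
        members = [GeneRole(g, float(rng.choice([-1.0, 1.0]))) for g in genes]
        stats_map = {g: _stat(g, float(rng.uniform(0.1, 10)), 1) for g in genes}
        pas = compute_pas(PathwayDefinition("P", "signaling", members), stats_map)
        shuffled = list(members)
        rng.shuffle(shuffled)
        pas2 = compute_pas(PathwayDefinition("P", "signaling", shuffled), stats_map)
        assert pas2 == pytest.approx(pas, rel=1e-12)


def _case_control(rng, genes, n_cases=3, n_ctrl=8):
    cases = ExpressionMatrix(
        pd.DataFrame(rng.lognormal(4, 0.5, (len(genes), n_cases)), index=genes,
                     columns=[f"s{i}" for i in range(n_cases)])
    )
    ctrl = ControlSet(
        "c1",
        ExpressionMatrix(
            pd.DataFrame(rng.lognormal(4, 0.5, (len(genes), n_ctrl)), index=genes,
                         columns=[f"c{i}" for i in range(n_ctrl)])
        ),
    )
    return cases, ctrl


class TestPASProfile:
    def test_unperturbed_tight_case_gives_zero_profile(self, rng):
        genes = ["A", "B", "C"]
        ctrl_df = pd.DataFrame(
            rng.normal(100, 5, (3, 10)), index=genes,
            columns=[f"c{i}" for i in range(10)],
        ).abs()
        cases = ExpressionMatrix(
            pd.DataFrame({"s1": ctrl_df.mean(axis=1)}, index=genes)
        )
        ctrl = ControlSet("c1", ExpressionMatrix(ctrl_df))
        db = [PathwayDefinition("P", "signaling", [GeneRole(g, 1.0) for g in genes])]
        profile = compute_pas_profile(cases, ctrl, db, PASParams(quantile=False))
        assert (profile.data.to_numpy() == 0).all()

    def test_planted_activator_upshift_gives_positive_pas(self, rng):
        genes = [f"G{i}" for i in range(5)]
        ctrl_df = pd.DataFrame(
            np.abs(rng.normal(100, 2, (5, 12))), index=genes,
            columns=[f"c{i}" for i in range(12)],
        )
        cases = ExpressionMatrix(
            pd.DataFrame({"s1": ctrl_df.mean(axis=1) * 4.0}, index=genes)
        )
        ctrl = ControlSet("c1", ExpressionMatrix(ctrl_df))
        db = [PathwayDefinition("P", "signaling", [GeneRole(g, 1.0) for g in genes])]
        profile = compute_pas_profile(cases, ctrl, db, PASParams(quantile=False))
        assert profile.data.loc["P", "s1"] > 0

    def test_profile_composes_gene_level_oracles(self, rng, random_db):
        """The vectorized profile equals composing the scalar CNR/BTIF/PAS
        operations gene by gene on the same normalized matrix."""
        genes = sorted({m.gene_symbol for pw in random_db[:5] for m in pw.members})
        cases, ctrl = _case_control(rng, genes)
        params = PASParams()
        profile = compute_pas_profile(cases, ctrl, random_db[:5], params)

        joint = join_case_control(cases, ctrl)
        norm = quantile_normalize_frame(joint.data)
        ctrl_cols = [s for s in norm.columns if joint.sample_labels[s] == "control"]
        for sample in cases.samples:
            stats_map = {}
            for g in norm.index:
                ctrl_vals = norm.loc[g, ctrl_cols].to_numpy(dtype=float)
                case_val = float(norm.loc[g, sample])
                btif, _ = compute_btif(case_val, ctrl_vals)
                stats_map[g] = GeneStat(g, compute_cnr(case_val, ctrl_vals), btif)
            for pw in random_db[:5]:
                expected = compute_pas(pw, stats_map)
                assert profile.data.loc[pw.pathway_id, sample] == pytest.approx(
                    expected, rel=1e-10, abs=1e-12
                )

    def test_limit_parameters_recover_unfiltered_signed_sum(self, rng):
        """With the normal band shrunk to {1} and alpha_gene = 1, every gene
        is flagged and PAS becomes the plain signed sum of log-ratios."""
        genes = [f"G{i}" for i in range(6)]
        cases, ctrl = _case_control(rng, genes, n_cases=2)
        members = [GeneRole(g, float(rng.choice([-1.0, -0.5, 0.5, 1.0]))) for g in genes]
        db = [PathwayDefinition("P", "signaling", members)]
        params = PASParams(alpha_gene=1.0, low_thresh=1 - 1e-12,
                           high_thresh=1 + 1e-12, quantile=False)
        profile = compute_pas_profile(cases, ctrl, db, params)
        ctrl_mean = ctrl.matrix.data.mean(axis=1)
        arr = pd.Series({m.gene_symbol: m.arr for m in members})
        for sample in cases.samples:
            log_cnr = np.log10(cases.data[sample] / ctrl_mean)
            expected = float((arr * log_cnr[arr.index]).sum())
            assert profile.data.loc["P", sample] == pytest.approx(expected, rel=1e-10)

    def test_literal_polarity_flips_flags(self, rng):
        genes = [f"G{i}" for i in range(6)]
        cases, ctrl = _case_control(rng, genes, n_cases=2)
        db = [PathwayDefinition("P", "signaling",
                                [GeneRole(g, 1.0) for g in genes])]
        p1 = compute_pas_profile(cases, ctrl, db, PASParams(quantile=False))
        p2 = compute_pas_profile(
            cases, ctrl, db, PASParams(quantile=False, btif_polarity="literal")
        )
        # flags are complementary: the two contributions sum to the
        # unfiltered signed sum
        full = compute_pas_profile(
            cases, ctrl, db,
            PASParams(alpha_gene=1.0, low_thresh=1 - 1e-12, high_thresh=1 + 1e-12,
                      quantile=False),
        )
        np.testing.assert_allclose(
            p1.data.to_numpy() + p2.data.to_numpy(), full.data.to_numpy(),
            rtol=1e-10, atol=1e-12,
        )

    def test_coverage_threshold_enforced(self, rng):
        genes = ["A", "B"]
        cases, ctrl = _case_control(rng, genes)
        db = [PathwayDefinition("P", "signaling",
                                [GeneRole("A", 1.0), GeneRole("X", 1.0),
                                 GeneRole("Y", 1.0), GeneRole("Z", 1.0)])]
        with pytest.raises(ValueError, match="coverage"):
            compute_pas_profile(cases, ctrl, db, PASParams(min_gene_coverage=0.5))

    def test_profile_round_trip(self, tmp_path, rng, random_db):
        genes = sorted({m.gene_symbol for pw in random_db[:3] for m in pw.members})
        cases, ctrl = _case_control(rng, genes)
        profile = compute_pas_profile(cases, ctrl, random_db[:3])
        write_pas_profile(profile, tmp_path / "pas.tsv")
        back = read_pas_profile(tmp_path / "pas.tsv")
        assert back.control_id == profile.control_id
        assert back.params == profile.params
        np.testing.assert_allclose(back.data.to_numpy(), profile.data.to_numpy(),
                                   rtol=1e-9)
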