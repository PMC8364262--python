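"""Weight fitting: recovery, regularization, identifiability, evaluation."""

import numpy as np
import pytest

from radstaff import (
    CalibrationPanel,
    ObservedStaffing,
    PanelSpec,
    RoleVector,
    default_weight_table,
    estimate_staffing,
    evaluate_fit,
    fit_weights,
    generate_panel,
)
from radstaff.calibration import DEFAULT_GROUPS
from radstaff.roles import ROLES


@pytest.fixture(scope="module")
def noiseless_panel():
    spec = PanelSpec(n_centers=30, seed=7, noise_sd={r: 0.0 for r in ROLES})
    return generate_panel(spec, default_weight_table())


@pytest.fixture(scope="module")
def noiseless_fit(noiseless_panel):
    return fit_weights(noiseless_panel, default_weight_table(), ridge=0.0)


class TestParameterRecovery:
    def test_identifiable_rows_recovered_exactly(self, table, noiseless_fit):
        """A panel generated by the default grid returns the default grid."""
        res = noiseless_fit
        for role in ROLES:
            for group, items in DEFAULT_GROUPS.items():
                if group in res.identifiability[role]:
                    continue
                true = table.lookup(items[0]).weights.get(role)
                fitted = res.fitted.lookup(items[0]).weights.get(role)
                if true > 0:
                    assert fitted == pytest.approx(true, rel=1e-6)
                else:
                    assert abs(fitted) < 1e-6

    def test_noiseless_residuals_vanish(self, noiseless_fit):
        assert noiseless_fit.residuals.abs().max().max() < 1e-8

    def test_kkt_residual_below_tolerance(self, noiseless_fit):
        assert noiseless_fit.kkt_residual < 1e-8

    def test_fit_invariant_to_center_order(self, noiseless_panel):
        base = default_weight_table()
        res1 = fit_weights(noiseless_panel, base, ridge=1e-3)
        shuffled = CalibrationPanel(
            entries=list(reversed(noiseless_panel.entries)),
            metadata=noiseless_panel.metadata,
        )
        res2 = fit_weights(shuffled, base, ridge=1e-3)
        assert res1.fitted.to_dict() == res2.fitted.to_dict()


class TestRegularization:
    def test_ridge_biases_toward_base_monotonically(self, table):
        """Stronger ridge pulls a perturbed-truth fit back toward the base."""
        from dataclasses import replace

        truth = default_weight_table()
        for item in ("linac", "gamma_knife"):  # rows share a fitted parameter
            row = truth.rows[item]
            truth.rows[item] = replace(
                row, weights=row.weights.with_role("physicist", 0.30)
            )
        spec = PanelSpec(n_centers=30, seed=11, noise_sd={r: 0.0 for r in ROLES})
        panel = generate_panel(spec, truth)
        base = default_weight_table()  # base linac physicist weight is 0.20
        gaps = []
        for ridge in (0.0, 1e-2, 1.0, 100.0):
            res = fit_weights(panel, base, ridge=ridge)
            gaps.append(abs(
                res.fitted.lookup("linac").weights.physicist - 0.20
            ))
        assert all(a >= b - 1e-12 for a, b in zip(gaps, gaps[1:]))
        assert gaps[0] == pytest.approx(0.10, abs=1e-4)

    def test_single_center_ridge_stays_near_base(self, table):
        spec = PanelSpec(n_centers=1, seed=3, noise_sd={r: 0.0 for r in ROLES})
        panel = generate_panel(spec, table)
        res = fit_weights(panel, table, ridge=1e-3)
        # data-poor limit: residual small, weights shifted only minimally
        assert res.residuals.abs().max().max() < 0.2
        for group, items in DEFAULT_GROUPS.items():
            for role in ROLES:
                base_w = table.lookup(items[0]).weights.get(role)
                fit_w = res.fitted.lookup(items[0]).weights.get(role)
                assert abs(fit_w - base_w) < 0.25

    def test_negative_ridge_rejected(self, noiseless_panel, table):
        with pytest.raises(ValueError):
            fit_weights(noiseless_panel, table, ridge=-1.0)

    def test_structural_row_cannot_be_freed(self, noiseless_panel, table):
        with pytest.raises(ValueError, match="structural"):
            fit_weights(
                noiseless_panel, table,
                free_groups={"coverage": ("coverage",)},
            )


class TestIdentifiability:
    def test_absent_equipment_flagged_not_zeroed(self, table, noiseless_fit):
        """Rows with no panel exposure keep base weights and are flagged."""
        res = noiseless_fit
        flagged = res.unidentifiable()
        for group in flagged:
            items = DEFAULT_GROUPS[group]
            for role in ROLES:
                assert res.fitted.lookup(items[0]).weights.get(role) == (
                    table.lookup(items[0]).weights.get(role)
                )

    def test_identical_centers_cause_rank_deficiency_flags(self, table):
        spec = PanelSpec(n_centers=1, seed=5, noise_sd={r: 0.0 for r in ROLES})
        panel = generate_panel(spec, table)
        clones = CalibrationPanel(
            entries=[
                (
                    inv.model_copy(update={"center_id": f"c{k}"}),
                    ObservedStaffing(center_id=f"c{k}", actual=obs.actual),
                )
                for k in range(5)
                for inv, obs in panel.entries
            ]
        )
        res = fit_weights(clones, table, ridge=0.0)
        # one distinct design row cannot identify ~20 parameters
        assert len(res.identifiability["physicist"]) > 10

    def test_default_panel_identifies_most_groups(self, noiseless_fit):
        """Default-spec diversity at n=30 pins down nearly every free row."""
        for role in ROLES:
            assert len(noiseless_fit.identifiability[role]) <= 2


class TestEvaluateFit:
    def test_exact_predictions_give_zero_summary(self, table):
        spec = PanelSpec(n_centers=5, seed=2, noise_sd={r: 0.0 for r in ROLES})
        panel = generate_panel(spec, table)
        summary = evaluate_fit(panel, table)
        overall = summary[summary.group == "overall"]
        assert np.allclose(overall.mean_diff, 0.0, atol=1e-10)
        assert np.allclose(overall.sd, 0.0, atol=1e-10)

    def test_closed_form_two_center_statistics(self, table):
        spec = PanelSpec(n_centers=2, seed=4, noise_sd={r: 0.0 for r in ROLES})
        panel = generate_panel(spec, table)
        # shift observed physicist staffing by -1 and +1 FTE
        entries = []
        for shift, (inv, obs) in zip((-1.0, 1.0), panel.entries):
            actual = obs.actual.with_role(
                "physicist", obs.actual.physicist + shift
            )
            entries.append(
                (inv, ObservedStaffing(center_id=inv.center_id, actual=actual))
            )
        summary = evaluate_fit(CalibrationPanel(entries=entries), table)
        phys = summary[(summary.group == "overall") & (summary.role == "physicist")]
        assert phys.mean_diff.iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert phys.sd.iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_group_means_recombine_to_overall(self, table):
        spec = PanelSpec(n_centers=8, seed=6)
        panel = generate_panel(spec, table)
        ids = [inv.center_id for inv, _ in panel.entries]
        grouping = {cid: ("east" if i < 3 else "west") for i, cid in enumerate(ids)}
        summary = evaluate_fit(panel, table, grouping=grouping)
        for role in ROLES:
            block = summary[summary.role == role].set_index("group")
            weighted = (
                block.loc["east", "mean_diff"] * block.loc["east", "n"]
                + block.loc["west", "mean_diff"] * block.loc["west", "n"]
            ) / (block.loc["east", "n"] + block.loc["west", "n"])
            assert weighted == pytest.approx(block.loc["overall", "mean_diff"])

    def test_summary_recomputable_from_residuals(self, noiseless_panel):
        res = fit_weights(noiseless_panel, default_weight_table(), ridge=1e-3)
        for role in ROLES:
            assert res.summary.loc[role, "mean_diff"] == pytest.approx(
                res.residuals[role].mean()
            )
            assert res.summary.loc[role, "sd"] == pytest.approx(
                res.residuals[role].std(ddof=1)
            )
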