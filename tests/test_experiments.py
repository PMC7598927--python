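"""In-silico experiment drivers: directional claims on shipped seeds.

The directional assertions (bigger populations with retention, shorter
generation times and longer health spans under declining repair capacity,
smaller populations under stress) are regression tests pinned to the shipped
wildtype configuration and fixed seeds; they encode qualitative behaviour of
this parameterisation, not universal theorems.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rejuvasim.experiments import (ExperimentDesign, matched_repair_rate,
                                   run_correlation_analysis,
                                   run_division_age_analysis,
                                   run_growth_rate_experiment,
                                   run_mixed_effects_comparison,
                                   run_stress_experiment,
                                   run_wildtype_population)
from rejuvasim.metrics import mean_rls, metrics_table


def arm(df, **kw):
    m = pd.Series(True, index=df.index)
    for k, v in kw.items():
        m &= df[k] == v
    return df[m]


# --------------------------------------------------------------------------
# retention sweep (shared session fixture)

def test_retention_gives_larger_populations(sweep_df):
    for regime in ("decline", "unlimited"):
        sizes = arm(sweep_df, regime=regime).set_index("re")["population_size"]
        assert sizes[0.2957] > sizes[0.0]


def test_retention_lowers_mean_damage_at_birth(sweep_df):
    for regime in ("decline", "unlimited"):
        dmg = arm(sweep_df, regime=regime).set_index("re")["mean_damage_at_birth"]
        assert dmg[0.2957] < dmg[0.0]


def test_retention_reduces_rls_dispersion(sweep_df):
    for regime in ("decline", "unlimited"):
        sd = arm(sweep_df, regime=regime).set_index("re")["sd_rls"]
        assert sd[0.2957] < sd[0.0]


def test_decline_shortens_generation_times(sweep_df):
    for re in (0.0, 0.2957):
        gt = arm(sweep_df, re=re).set_index("regime")["mean_generation_time"]
        assert gt["decline"] < gt["unlimited"]


def test_decline_prolongs_health_spans(sweep_df):
    for re in (0.0, 0.2957):
        h = arm(sweep_df, re=re).set_index("regime")["mean_health_span"]
        assert h["decline"] > h["unlimited"]


def test_retention_reduces_dispersion_across_lineage_grid(small_design):
    # sd of rls across (i, j) groups shrinks with retention (sigma = 0)
    from rejuvasim.metrics import group_by_lineage_position
    sds = {}
    for re in (0.0, 0.2957):
        table = run_wildtype_population(
            small_design, regime="decline", re=re, sigma=0.0, n_founders=1)
        grouped = group_by_lineage_position(table, "rls")
        sds[re] = float(grouped["mean"].std(ddof=1))
    assert sds[0.2957] < sds[0.0]


def test_sweep_reruns_identically(small_design):
    from rejuvasim.experiments import run_retention_sweep
    d = small_design.with_updates(n_founders=1, re_values=(0.2957,),
                                  regimes=("decline",))
    a = run_retention_sweep(d)
    b = run_retention_sweep(d)
    pd.testing.assert_frame_equal(a, b)


# --------------------------------------------------------------------------
# division-age analysis

@pytest.fixture(scope="module")
def division_age_df(small_design):
    return run_division_age_analysis(
        small_design.with_updates(n_founders=2))


def test_mother_damage_share_constant_over_ages(division_age_df):
    ret = division_age_df[division_age_df["re"] == 0.2957]
    share = ret["mother_D"] / (ret["mother_D"] + ret["daughter_D"])
    assert np.allclose(share, 0.64 + 0.2957 * 0.36, rtol=1e-12)
    non = division_age_df[division_age_df["re"] == 0.0]
    share0 = non["mother_D"] / (non["mother_D"] + non["daughter_D"])
    assert np.allclose(share0.dropna(), 0.64, rtol=1e-12)


def test_first_division_daughter_damage_follows_rule(small_design):
    table = run_wildtype_population(small_design, regime="decline",
                                    re=0.2957, sigma=0.0, n_founders=1)
    founder = table[table.founders[0]]
    first_daughter = table[founder.daughter_ids[0]]
    params = founder.params
    S1 = founder.sizes_at_divisions[0]
    D_pre = (S1 - params.P_div) / params.Q
    expected = (1 - params.re) * (1 - params.s) * D_pre
    assert first_daughter.birth_state.D == pytest.approx(expected, rel=1e-9)


def test_retention_lowers_daughter_damage_at_every_age(division_age_df):
    dec = division_age_df[division_age_df["regime"] == "decline"]
    by_age = dec.groupby(["re", "mother_age"])["daughter_D"].mean().unstack("re")
    both = by_age.dropna()
    assert (both[0.2957] < both[0.0]).all()


# --------------------------------------------------------------------------
# growth rate

def test_snapshot_before_first_division_counts_founder_only(small_design):
    d = small_design.with_updates(snapshot_time=0.1, n_populations=1,
                                  re_values=(0.2957,), regimes=("decline",))
    df = run_growth_rate_experiment(d)
    assert (df["cells_at_snapshot"] == 1).all()


def test_decline_grows_faster_at_snapshot(growth_df):
    dec = arm(growth_df, regime="decline")["cells_at_snapshot"]
    unl = arm(growth_df, regime="unlimited")["cells_at_snapshot"]
    assert dec.mean() > unl.mean()
    res = stats.mannwhitneyu(dec, unl, alternative="greater")
    assert res.pvalue < 0.05


def test_snapshot_counts_match_exported_filter(small_design, tmp_path):
    from rejuvasim.lineage import export_lineage
    d = small_design.with_updates(n_populations=1, re_values=(0.2957,))
    df = run_growth_rate_experiment(d.with_updates(regimes=("decline",)))
    table = run_wildtype_population(d, regime="decline", re=0.2957,
                                    n_founders=1, seed=d.seed,
                                    t_spawn_horizon=d.snapshot_time)
    csv_path, _ = export_lineage(table, tmp_path)
    redone = int((pd.read_csv(csv_path)["t0"] <= d.snapshot_time).sum())
    assert int(df["cells_at_snapshot"].iloc[0]) == redone


# --------------------------------------------------------------------------
# stress

def test_unit_stress_multiplier_is_identity(small_design):
    d = small_design.with_updates(re_values=(0.2957,), regimes=("decline",),
                                  stress_multiplier=1.0)
    df = run_stress_experiment(d)
    a = arm(df, arm="stressed").reset_index(drop=True).drop(columns=["arm", "k1_scale"])
    b = arm(df, arm="unstressed").reset_index(drop=True).drop(columns=["arm", "k1_scale"])
    pd.testing.assert_frame_equal(a, b)


def test_stress_scales_sampled_rates_exactly(small_design):
    tables = {}
    for scale in (1.0, 1.01):
        tables[scale] = run_wildtype_population(
            small_design, regime="decline", re=0.2957, k1_scale=scale,
            n_founders=1)
    by_pos = {r.position: r.params.k1 for r in tables[1.0]}
    for r in tables[1.01]:
        if r.position in by_pos:
            assert r.params.k1 == pytest.approx(1.01 * by_pos[r.position],
                                                rel=1e-14)


def test_stress_shrinks_populations(stress_df):
    sizes = stress_df.groupby(["regime", "re", "arm"])["population_size"].first()
    for regime in ("decline", "unlimited"):
        for re in (0.0, 0.2957):
            assert sizes[regime, re, "stressed"] < sizes[regime, re, "unstressed"]


# --------------------------------------------------------------------------
# mixed effects

@pytest.fixture(scope="module")
def sigma_df(small_design):
    return run_mixed_effects_comparison(
        small_design.with_updates(re_values=(0.2957,), regimes=("decline",)))


def test_homogeneous_population_has_smaller_rls_dispersion(sigma_df):
    by_sigma = sigma_df.set_index("sigma")
    assert by_sigma.loc[0.0, "sd_rls"] < by_sigma.loc[0.005, "sd_rls"]
    assert by_sigma.loc[0.005, "sd_rls"] > 0


def test_population_size_stable_across_sigma_modes(sigma_df):
    by_sigma = sigma_df.set_index("sigma")["population_size"]
    rel = abs(by_sigma[0.005] - by_sigma[0.0]) / by_sigma[0.0]
    assert rel < 0.10


def test_sigma_zero_replicate_populations_identical(small_design):
    frames = []
    for _ in range(2):
        table = run_wildtype_population(small_design, regime="decline",
                                        re=0.2957, sigma=0.0, n_founders=2)
        frames.append(metrics_table(table))
    pd.testing.assert_frame_equal(frames[0], frames[1])
    # the two founders' subtrees are indistinguishable cell-for-cell
    df = frames[0]
    t = run_wildtype_population(small_design, regime="decline", re=0.2957,
                                sigma=0.0, n_founders=2)
    by_founder = {}
    for r in t:
        by_founder.setdefault(r.founder_index, {})[r.position] = r.rls
    assert by_founder[0] == by_founder[1]


# --------------------------------------------------------------------------
# correlation analysis

def test_correlation_outputs_join_back_to_cells(small_table):
    design = ExperimentDesign(seed=1)
    df = run_correlation_analysis(design, table=small_table)
    cells = metrics_table(small_table)
    assert set(df["cell_id"]).issubset(set(cells["cell_id"]))
    assert set(df["pairing"]) == {
        "health_span~rls", "mean_generation_time~mean_growth_per_cycle",
        "i~rls", "size_at_birth~cumulative_growth"}


def test_rejuvenated_flag_matches_recomputed_index(small_table):
    design = ExperimentDesign(seed=1)
    df = run_correlation_analysis(design, table=small_table)
    mbar = mean_rls(small_table)
    for _, row in df[df["pairing"] == "i~rls"].head(50).iterrows():
        rec = small_table[int(row["cell_id"])]
        if rec.mother_id is None:
            assert not row["rejuvenated"]
            continue
        rej = (rec.rls - small_table[rec.mother_id].rls) / mbar
        assert row["rejuvenated"] == (rej > 0)
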