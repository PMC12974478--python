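import dataclasses

import numpy as np
import pytest

from dualscale.experiments import (PROFILES, aggregate_and_report,
                                   latency_table, reconfigure_model,
                                   run_model, run_protocol_experiment)
from dualscale.protocol import build_schedule


def test_profiles_defined():
    assert PROFILES["full"]["pert_s"] == 1800.0
    assert PROFILES["ci"]["pert_s"] == 300.0


def test_full_run_measures_everything(ci_runs):
    result = ci_runs["full"]
    assert result.error is None
    assert len(result.latencies) == 3
    assert len(result.wash_classes) == 3
    assert result.g_summary is not None
    assert set(result.g_summary["norms"]) == {
        "After Pert 1", "After Wash 1", "After Pert 2",
        "After Wash 2", "After Pert 3", "After Wash 3"}
    assert result.g_summary["snapshots"].shape == (7, 7)
    assert result.shift_summary["snapshots"].shape == (7, 11)


class TestReconfigure:
    def test_keep_final_gmax(self, reference_member, ci_schedule, ci_runs):
        source = run_protocol_experiment([reference_member], "full",
                                         schedule=ci_schedule, dt=0.1,
                                         profile="ci")
        final = source.models[0].final_intrinsic
        reconf = reconfigure_model(reference_member, source, "final_gmax")
        assert np.array_equal(reconf.intrinsic.gmax, final.gmax)
        assert np.array_equal(reconf.intrinsic.half_shifts,
                              reference_member.intrinsic.half_shifts)

    def test_keep_final_halfshifts(self, reference_member, ci_schedule):
        source = run_protocol_experiment([reference_member], "full",
                                         schedule=ci_schedule, dt=0.1,
                                         profile="ci")
        final = source.models[0].final_intrinsic
        reconf = reconfigure_model(reference_member, source,
                                   "final_halfshifts")
        assert np.array_equal(reconf.intrinsic.half_shifts,
                              final.half_shifts)
        assert np.array_equal(reconf.intrinsic.gmax,
                              reference_member.intrinsic.gmax)

    def test_frozen_source_reproduces_original(self, reference_member,
                                               ci_schedule):
        # a run with both processes frozen leaves the parameters untouched,
        # so both reconfigurations reproduce the original model exactly
        frozen = run_protocol_experiment([reference_member], "half_only",
                                         schedule=ci_schedule, dt=0.1,
                                         profile="ci")
        res = frozen.models[0]
        # freeze shifts too by reconfiguring from initial == final gmax
        assert np.array_equal(res.final_intrinsic.gmax,
                              reference_member.intrinsic.gmax)
        reconf = reconfigure_model(reference_member, frozen, "final_gmax")
        assert np.array_equal(reconf.intrinsic.gmax,
                              reference_member.intrinsic.gmax)

    def test_bad_keep_rejected(self, reference_member, ci_schedule):
        source = run_protocol_experiment([reference_member], "half_only",
                                         schedule=ci_schedule, dt=0.1,
                                         profile="ci")
        with pytest.raises(ValueError):
            reconfigure_model(reference_member, source, "everything")


def test_manifest_replay_bit_identical(reference_member, ci_schedule):
    r1 = run_protocol_experiment([reference_member], "full",
                                 schedule=ci_schedule, dt=0.1, profile="ci")
    r2 = run_protocol_experiment([reference_member], "full",
                                 schedule=ci_schedule, dt=0.1, profile="ci")
    assert r1.manifest == r2.manifest
    m1, m2 = r1.models[0], r2.models[0]
    assert m1.latencies == m2.latencies
    assert np.array_equal(m1.g_summary["snapshots"],
                          m2.g_summary["snapshots"])
    assert np.array_equal(m1.final_intrinsic.gmax, m2.final_intrinsic.gmax)


def test_aggregate_report_consistency(reference_member, ci_schedule):
    result = run_protocol_experiment([reference_member], "full",
                                     schedule=ci_schedule, dt=0.1,
                                     profile="ci")
    report = aggregate_and_report([result])
    entry = report["full:ci"]
    lat = entry["latency"]
    # medians in the report equal direct medians of the latency table
    direct = lat.groupby("perturbation_index")["latency_s"].median()
    assert entry["latency_medians"].equals(direct)
    assert entry["latency_missing"] == int(lat["latency_s"].isna().sum())
    counts = entry["counts"]
    assert counts["n_models"] == 1
    assert set(entry["conductance_trajectories"].columns) >= {
        "radius", "outside_distance", "After Pert 1"}


def test_unknown_variant_rejected(reference_member):
    with pytest.raises(ValueError):
        run_protocol_experiment([reference_member], "sideways", profile="ci")


def test_missing_latency_reported_as_nan(reference_member, ci_schedule):
    res = run_protocol_experiment([reference_member], "half_only",
                                  schedule=ci_schedule, dt=0.1, profile="ci")
    tab = latency_table(res)
    assert len(tab) == 3
    assert tab["latency_s"].dtype == float  # Nones became NaN
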