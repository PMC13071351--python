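"""Sweep orchestration, presets, config handling and CLI plumbing."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import metaecosim as me
from metaecosim.cli import main as cli_main
from metaecosim.config import axis_values, build_settle, load_config, save_config
from metaecosim.sweeps import write_manifest


def _tiny_spec(**kw):
    defaults = dict(
        d_N_values=[0.0],
        d_C_values=[0.1],
        n_ic=2,
        seed=5,
        settle=me.SettleSettings().fast(),
    )
    defaults.update(kw)
    return me.SweepSpec(**defaults)


def test_state_diagram_uncoupled_cell_is_homogeneous_equilibrium(tmp_path):
    out = tmp_path / "grid.csv"
    df = me.state_diagram(_tiny_spec(), out_path=out)
    assert df.loc[0, "state_code"] == "HOM_EQ"
    assert not df.loc[0, "bistable"]
    on_disk = pd.read_csv(out)
    assert on_disk.loc[0, "state_code"] == "HOM_EQ"


def test_sweeps_are_deterministic_given_seed():
    a = me.state_diagram(_tiny_spec())
    b = me.state_diagram(_tiny_spec())
    pd.testing.assert_frame_equal(a, b)


def test_bifurcation_consumer_envelope_collapses_at_equilibrium():
    spec = _tiny_spec(d_N_values=[0.0, 5.0])
    df = me.bifurcation_transect(spec, d_C=0.4)
    for _, row in df.iterrows():
        if row["state_code"].endswith("_EQ"):
            assert row["C_meta_max"] - row["C_meta_min"] < 1e-4


def test_stop_condition_short_circuits_scan():
    spec = _tiny_spec(d_N_values=[0.0, 0.1, 0.2, 5.0])
    df = me.bifurcation_transect(
        spec, d_C=0.4, stop_condition=lambda rows: len(rows) >= 2
    )
    assert len(df) == 2


def test_dispersal_plane_symmetric_cells_match():
    """(d_CA, d_CB) and (d_CB, d_CA) are equivalent under type relabelling."""
    spec = _tiny_spec(d_CA_values=[0.1, 0.4], d_CB_values=[0.1, 0.4])
    df = me.dispersal_plane(spec, d_N=5.0)
    ab = df[(df.d_CA == 0.1) & (df.d_CB == 0.4)].iloc[0]
    ba = df[(df.d_CA == 0.4) & (df.d_CB == 0.1)].iloc[0]
    assert ab["state_code"] == ba["state_code"]


def test_threshold_helpers():
    df = pd.DataFrame(
        {
            "d_N": [2.5, 2.6, 2.65, 3.0],
            "state_code": ["HOM_OSC", "MIXED", "HET_OSC", "HET_EQ"],
        }
    )
    assert me.smallest_dN_with_state(df) == 2.65
    assert me.smallest_dN_with_state(df, ["HET_EQ"]) == 3.0
    assert me.smallest_dN_with_state(df, ["FAILED"]) is None
    plane = pd.DataFrame(
        {
            "d_CA": [0.1, 0.2, 0.3],
            "d_CB": [0.4, 0.4, 0.4],
            "state_code": ["HOM_OSC", "HET_EQ", "HET_EQ"],
        }
    )
    assert me.critical_dispersal(plane, "d_CA", "d_CB", 0.4) == 0.2


def test_preset_construction():
    spec = me.spec_from_preset("ci", seed=3)
    assert spec.n_ic == 8
    assert spec.settle.t_max < me.SettleSettings().t_max
    spec2 = me.spec_from_preset("state-grid")
    assert spec2.n_ic == 50
    assert min(spec2.d_N_values) == 0.0 and max(spec2.d_N_values) == 5.0
    with pytest.raises(KeyError):
        me.spec_from_preset("bogus")


def test_manifest_round_trip(tmp_path):
    import json

    spec = _tiny_spec()
    write_manifest(tmp_path / "m.json", spec, {"note": "x"})
    m = json.loads((tmp_path / "m.json").read_text())
    assert m["seed"] == 5
    assert m["params"]["I_N"] == 0.05
    assert m["settle"]["t_max"] == spec.settle.t_max


def test_config_axis_and_strict_keys(tmp_path):
    assert list(axis_values({"start": 2.0, "stop": 2.2, "step": 0.1})) == [
        pytest.approx(v) for v in (2.0, 2.1, 2.2)
    ]
    assert list(axis_values([0.1, 0.4])) == [0.1, 0.4]
    with pytest.raises(KeyError):
        axis_values({"start": 0, "end": 1, "step": 0.1})
    cfg = {
        "params": {"d_CA": 0.4, "d_CB": 0.4},
        "settle": {"t_max": 50000.0},
    }
    path = tmp_path / "run.yaml"
    save_config(cfg, path)
    loaded = load_config(path)
    assert build_settle(loaded).t_max == 50000.0
    save_config({"parms": {}}, path)
    with pytest.raises(KeyError, match="section"):
        load_config(path)


def test_cli_simulate_smoke(tmp_path):
    runner = CliRunner()
    res = runner.invoke(
        cli_main,
        [
            "simulate",
            "--seed", "2",
            "--out", str(tmp_path),
            "--t-end", "2000",
            "--t-transient", "500",
        ],
    )
    assert res.exit_code == 0, res.output
    assert (tmp_path / "trajectory.csv").exists()
    assert (tmp_path / "report.json").exists()
    assert "HOM_EQ" in res.output or "state:" in res.output


def test_cli_bifurcation_with_config(tmp_path):
    cfg = tmp_path / "cfg.yaml"
    save_config(
        {
            "sweep": {"d_N": [0.0], "n_ic": 2},
            "settle": {"t_first": 10000.0, "t_max": 60000.0,
                       "chunk": 10000.0},
        },
        cfg,
    )
    runner = CliRunner()
    res = runner.invoke(
        cli_main,
        [
            "bifurcation",
            "--config", str(cfg),
            "--seed", "2",
            "--out", str(tmp_path / "out"),
            "--d-c", "0.1",
        ],
    )
    assert res.exit_code == 0, res.output
    df = pd.read_csv(tmp_path / "out" / "bifurcation.csv")
    assert df.loc[0, "state_code"] == "HOM_EQ"
    assert (tmp_path / "out" / "manifest.json").exists()
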