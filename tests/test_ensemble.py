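"""Synthetic parameter ensembles: generation, locality, coordinate realization."""

import numpy as np
import pytest

from modflex.constructs import ModifiedDuplex, apply_modifications
from modflex.ensemble import (
    DEFAULT_BASELINE,
    EnsembleSpec,
    ParameterEnsemble,
    condition_suite,
    default_effects,
    extract_parameters,
    generate_parameter_ensemble,
    read_multimodel_pdb,
    realize_coordinates,
    write_multimodel_pdb,
)

SEQ_21 = "ATACGATCCGGATTACGTTAG"  # CpG steps at 4, 9, 16


@pytest.fixture
def small_modified():
    return apply_modifications(ModifiedDuplex(SEQ_21), [4, 9], "5fC")


def make_spec(duplex, **kw):
    defaults = dict(n_frames=100, seed=11)
    defaults.update(kw)
    return EnsembleSpec(duplex=duplex, **defaults)


class TestGenerate:
    def test_deterministic_under_seed(self, small_modified):
        a = generate_parameter_ensemble(make_spec(small_modified))
        b = generate_parameter_ensemble(make_spec(small_modified))
        for name in a.values:
            assert np.array_equal(a.values[name], b.values[name])

    def test_zero_sd_degenerates_to_means(self):
        duplex = ModifiedDuplex(SEQ_21)
        baseline = {k: (m, 0.0) for k, (m, _) in DEFAULT_BASELINE.items()}
        ens = generate_parameter_ensemble(
            make_spec(duplex, baseline=baseline, n_frames=10)
        )
        assert np.allclose(ens.values["twist"], 36.0)
        assert np.allclose(ens.values["rise"], 3.38)
        assert np.allclose(ens.values["roll"], 0.0)

    def test_sd_shift_at_cpg_centre_recovered(self, small_modified):
        """+1 deg roll Δsd at the CpG step shows up in the sample sd within
        3 standard errors (SE(sd) ~ sd/sqrt(2n))."""
        n = 100_000
        effects = {m: {} for m in ("5mC", "5hmC", "5fC", "5caC")}
        effects["5fC"]["roll"] = (0.0, 1.0)
        ens = generate_parameter_ensemble(
            make_spec(small_modified, n_frames=n, effects=effects)
        )
        target_sd = DEFAULT_BASELINE["roll"][1] + 1.0
        se = target_sd / np.sqrt(2 * n)
        for step in (4, 9):
            sd = ens.series(step, "roll").std(ddof=1)
            assert abs(sd - target_sd) < 3 * se
        # far from any CpG step: baseline sd
        far_sd = ens.series(13, "roll").std(ddof=1)
        base = DEFAULT_BASELINE["roll"][1]
        assert abs(far_sd - base) < 3 * base / np.sqrt(2 * n)

    def test_moments_converge_at_root_n(self):
        """Mean absolute sd error across positions shrinks ~1/sqrt(n)."""
        duplex = ModifiedDuplex(SEQ_21)
        errs = []
        for n in (500, 8_000):
            ens = generate_parameter_ensemble(
                make_spec(duplex, n_frames=n, parameters=("roll",), seed=5)
            )
            sds = ens.values["roll"].std(axis=1, ddof=1)
            errs.append(np.mean(np.abs(sds - DEFAULT_BASELINE["roll"][1])))
        ratio = errs[0] / errs[1]
        assert 2.0 < ratio < 8.0  # expected 4 for a 16x sample increase

    def test_paired_seed_effects_are_local(self, small_modified):
        """With a shared seed, modified and unmodified ensembles are
        bit-identical outside the kernel support."""
        suite = condition_suite(
            ModifiedDuplex(SEQ_21), ["unmodified", "5fC"], cpg_steps=[4, 9],
            seed=3, shared_seed_policy="paired", n_frames=200,
        )
        un, fc = suite["unmodified"], suite["5fC"]
        # kernel support: steps within 2 of a CpG centre (weight 0 at |d|=3)
        affected = {s for c in (4, 9) for s in range(c - 2, c + 3)}
        for s_idx, pos in enumerate(un.step_positions):
            same = np.array_equal(un.values["roll"][s_idx], fc.values["roll"][s_idx])
            assert same == (pos not in affected)

    def test_negative_sd_floored_with_warning(self):
        duplex = apply_modifications(ModifiedDuplex(SEQ_21), [4], "5mC")
        effects = {m: {} for m in ("5mC", "5hmC", "5fC", "5caC")}
        effects["5mC"]["roll"] = (0.0, -50.0)
        with pytest.warns(UserWarning, match="floor"):
            ens = generate_parameter_ensemble(
                make_spec(duplex, effects=effects, parameters=("roll",))
            )
        assert ens.series(4, "roll").std() < 1e-3

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            make_spec(ModifiedDuplex(SEQ_21), neighbour_kernel={0: 0.5})


class TestConditionSuite:
    def test_five_conditions_identical_shapes(self, central_duplex):
        suite = condition_suite(
            central_duplex, ["unmodified", "5mC", "5hmC", "5fC", "5caC"],
            n_frames=20, parameters=("roll",),
        )
        assert set(suite) == {"unmodified", "5mC", "5hmC", "5fC", "5caC"}
        shapes = {e.values["roll"].shape for e in suite.values()}
        assert len(shapes) == 1

    def test_single_condition(self, central_duplex):
        suite = condition_suite(central_duplex, ["unmodified"], n_frames=5,
                                parameters=("roll",))
        assert list(suite) == ["unmodified"]

    def test_unknown_condition_rejected(self, central_duplex):
        with pytest.raises(ValueError, match="unknown condition"):
            condition_suite(central_duplex, ["6mA"], n_frames=5)


class TestRealizeExtract:
    def test_zero_fluctuation_ideal_bdna_recovered(self):
        """Deterministic chain: extraction reproduces the baseline means to
        1e-6."""
        duplex = ModifiedDuplex(SEQ_21)
        baseline = {k: (m, 0.0) for k, (m, _) in DEFAULT_BASELINE.items()}
        ens = generate_parameter_ensemble(make_spec(duplex, baseline=baseline, n_frames=2))
        stack, coords = realize_coordinates(ens, duplex, return_coords=True)
        out = extract_parameters(stack, coords=coords)
        for name, arr in out.values.items():
            mean, _ = {**DEFAULT_BASELINE}[name]
            assert np.allclose(arr, mean, atol=1e-6), name

    def test_full_roundtrip_recovers_sampled_values(self, small_modified):
        ens = generate_parameter_ensemble(make_spec(small_modified, n_frames=8))
        stack, coords = realize_coordinates(ens, small_modified, return_coords=True)
        out = extract_parameters(stack, coords=coords)
        for name in ens.values:
            assert np.max(np.abs(ens.values[name] - out.values[name])) < 1e-8, name

    def test_pdb_roundtrip_preserves_coordinates(self, small_modified, tmp_path):
        """PDB carries 3 decimals: coordinates survive write/read to 1e-3 Å."""
        ens = generate_parameter_ensemble(make_spec(small_modified, n_frames=3))
        stack = realize_coordinates(ens, small_modified)
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(path, stack, seed=11, spec_hash="abc")
        again = read_multimodel_pdb(path)
        assert again.stack_depth() == 3
        assert np.max(np.abs(stack.coord - again.coord)) <= 1e-3
        assert "seed=11" in path.read_text().splitlines()[1]

    def test_partial_ensemble_rejected(self, small_modified):
        ens = generate_parameter_ensemble(
            make_spec(small_modified, parameters=("roll", "twist"))
        )
        with pytest.raises(ValueError, match="lacks parameters"):
            realize_coordinates(ens, small_modified)


class TestParameterEnsembleIO:
    def test_tsv_roundtrip(self, small_modified, tmp_path):
        ens = generate_parameter_ensemble(make_spec(small_modified, n_frames=4))
        path = tmp_path / "ens.tsv"
        ens.to_tsv(path)
        again = ParameterEnsemble.from_tsv(path)
        assert again.condition == ens.condition
        assert again.seed == ens.seed
        assert again.frame_interval_ps == ens.frame_interval_ps
        for name in ens.values:
            assert np.allclose(ens.values[name], again.values[name], atol=1e-12)

    def test_series_lookup_by_position(self, small_modified):
        ens = generate_parameter_ensemble(make_spec(small_modified, n_frames=4))
        assert ens.series(1, "roll").shape == (4,)
        with pytest.raises(KeyError):
            ens.series(999, "roll")


def test_default_effects_ordering():
    """Synthetic calibration preserves the flexibility ordering on Δsd."""
    centre = {m: default_effects(m)["roll"][1] for m in ("5fC", "5hmC", "5caC", "5mC")}
    assert centre["5fC"] > centre["5hmC"] > centre["5caC"] > 0 > centre["5mC"]
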