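"""Metastatic-potential estimators: formula micro-examples, bootstrap
behaviour, penetrance, and scale equivariance."""

import numpy as np
import pandas as pd
import pytest

from metpool.barcode_quant import CompositionEstimate, estimate_composition
from metpool.core_io import (
    BarcodeCountTable,
    CellCountTable,
    SampleMeta,
)
from metpool.potential import (
    absolute_potential,
    bootstrap_ci,
    export_petal,
    overall_potential,
    penetrance,
    relative_potential,
)

from conftest import make_library


def _composition(values, samples):
    values = np.asarray(values, dtype=float)
    return CompositionEstimate(
        fractions=values,
        assigned_total=np.full(values.shape[1], 1000),
        barcode_ids=[f"B{i}" for i in range(values.shape[0])],
        samples=samples,
    )


class TestAbsolutePotential:
    def test_single_mouse_formula(self):
        comp = _composition(
            [[0.2], [0.8]], [SampleMeta("s1", "m1", "brain")]
        )
        cells = CellCountTable({("m1", "brain"): 100000})
        table = absolute_potential(comp, cells, B=50, seed=0)
        i = table.lines.index("B0")
        assert table.potential[i, 0] == pytest.approx(20000)

    def test_mean_over_mice(self):
        comp = _composition(
            [[0.2, 0.1], [0.8, 0.9]],
            [SampleMeta("s1", "m1", "brain"), SampleMeta("s2", "m2", "brain")],
        )
        cells = CellCountTable({("m1", "brain"): 100000, ("m2", "brain"): 200000})
        table = absolute_potential(comp, cells, B=50, seed=0)
        i = table.lines.index("B0")
        assert table.potential[i, 0] == pytest.approx((20000 + 20000) / 2)

    def test_absent_line_is_zero(self):
        comp = _composition(
            [[0.0, 0.0], [1.0, 1.0]],
            [SampleMeta("s1", "m1", "brain"), SampleMeta("s2", "m2", "brain")],
        )
        cells = CellCountTable({("m1", "brain"): 1e5, ("m2", "brain"): 2e5})
        table = absolute_potential(comp, cells, B=50, seed=0)
        assert table.potential[table.lines.index("B0"), 0] == 0.0

    def test_missing_cell_count_names_mouse_and_organ(self):
        comp = _composition([[1.0]], [SampleMeta("s1", "m9", "lung")])
        with pytest.raises(ValueError, match="m9.*lung"):
            absolute_potential(comp, CellCountTable({}), B=10, seed=0)


def _table(library, counts, samples):
    arr = np.asarray(counts)
    return BarcodeCountTable(counts=arr, library=library, samples=samples)


class TestRelativePotential:
    def test_identical_to_preinjection_gives_one(self, rng):
        lib = make_library(rng, 3, 12)
        organ = _table(
            lib, [[500], [300], [200]], [SampleMeta("o1", "m1", "brain")]
        )
        pre = _table(
            lib, [[500], [300], [200]], [SampleMeta("p1", organ="pre_injection")]
        )
        pot = relative_potential(organ, pre, B=50, seed=0)
        assert np.allclose(pot.potential[:, 0], 1.0)

    def test_zero_organ_counts_give_zero(self, rng):
        lib = make_library(rng, 2, 12)
        organ = _table(lib, [[0], [100]], [SampleMeta("o1", "m1", "lung")])
        pre = _table(lib, [[50], [50]], [SampleMeta("p1", organ="pre_injection")])
        pot = relative_potential(organ, pre, B=50, seed=0)
        assert pot.potential[0, 0] == 0.0

    def test_cpm_ratio_hand_example(self, rng):
        # organ {A:800, B:200} vs pre {A:500, B:500}: rM = {1.6, 0.4}
        lib = make_library(rng, 2, 12)
        organ = _table(lib, [[800], [200]], [SampleMeta("o1", "m1", "brain")])
        pre = _table(lib, [[500], [500]], [SampleMeta("p1", organ="pre_injection")])
        pot = relative_potential(organ, pre, B=50, seed=0)
        assert pot.potential[:, 0] == pytest.approx([1.6, 0.4])

    def test_line_absent_preinjection_is_nan_with_warning(self, rng):
        lib = make_library(rng, 2, 12)
        organ = _table(lib, [[10], [90]], [SampleMeta("o1", "m1", "brain")])
        pre = _table(lib, [[0], [100]], [SampleMeta("p1", organ="pre_injection")])
        with pytest.warns(UserWarning, match="absent"):
            pot = relative_potential(organ, pre, B=50, seed=0)
        assert np.isnan(pot.potential[0, 0])
        assert np.isfinite(pot.potential[1, 0])

    def test_scale_equivariance(self, rng):
        """Multiplying every organ sample by a constant leaves rM unchanged."""
        lib = make_library(rng, 4, 12)
        counts = rng.integers(1, 1000, size=(4, 3))
        samples = [SampleMeta(f"o{k}", f"m{k}", "bone") for k in range(3)]
        pre = _table(
            lib, rng.integers(100, 1000, size=(4, 2)),
            [SampleMeta(f"p{r}", organ="pre_injection") for r in range(2)],
        )
        pot1 = relative_potential(_table(lib, counts, samples), pre, B=10, seed=3)
        pot2 = relative_potential(_table(lib, counts * 17, samples), pre, B=10, seed=3)
        assert np.allclose(pot1.potential, pot2.potential)


class TestPenetrance:
    def test_detection_rule_counts_mice(self, rng):
        lib = make_library(rng, 1, 12)
        counts = np.array([[6, 4, 0, 12, 5]])
        samples = [SampleMeta(f"s{k}", f"m{k}", "brain") for k in range(5)]
        pen = penetrance(_table(lib, counts, samples), min_reads=5)
        assert pen.iloc[0, 0] == pytest.approx(3 / 5)

    def test_extremes(self, rng):
        lib = make_library(rng, 2, 12)
        counts = np.array([[10] * 5, [0] * 5])
        samples = [SampleMeta(f"s{k}", f"m{k}", "liver") for k in range(5)]
        pen = penetrance(_table(lib, counts, samples), min_reads=5)
        assert pen.iloc[0, 0] == 1.0
        assert pen.iloc[1, 0] == 0.0

    def test_min_fraction_rule(self, rng):
        lib = make_library(rng, 2, 12)
        counts = np.array([[99, 10], [1, 90]])
        samples = [SampleMeta(f"s{k}", f"m{k}", "kidney") for k in range(2)]
        pen = penetrance(_table(lib, counts, samples), min_fraction=0.05)
        assert pen.iloc[0, 0] == 1.0  # 0.99 and 0.10 both pass
        assert pen.iloc[1, 0] == 0.5  # 0.01 fails, 0.90 passes


class TestBootstrapCI:
    def test_zero_variance_collapses(self):
        lo, hi = bootstrap_ci(np.full(8, 3.5), B=200, seed=1)
        assert lo == pytest.approx(3.5) and hi == pytest.approx(3.5)

    def test_deterministic_given_seed(self, rng):
        v = rng.lognormal(0, 1, size=10)
        a = bootstrap_ci(v, B=500, seed=42)
        b = bootstrap_ci(v, B=500, seed=42)
        assert a == b

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones(5), B=0)
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones(5), level=1.5)

    def test_interval_widens_with_spread(self, rng):
        tight = rng.normal(10, 0.1, size=12)
        wide = rng.normal(10, 5.0, size=12)
        lo1, hi1 = bootstrap_ci(tight, B=500, seed=0)
        lo2, hi2 = bootstrap_ci(wide, B=500, seed=0)
        assert (hi2 - lo2) > (hi1 - lo1)


class TestOverallPotential:
    def _pot(self, rM, rng):
        lib = make_library(rng, rM.shape[0], 12)
        from metpool.potential import PotentialTable

        return PotentialTable(
            lines=[f"L{i}" for i in range(rM.shape[0])],
            organs=["bone", "brain", "kidney", "liver", "lung"][: rM.shape[1]],
            potential=rM,
            ci_low=rM,
            ci_high=rM,
            penetrance=np.ones_like(rM),
            n_mice=np.full(rM.shape[1], 5),
            kind="relative",
        )

    def test_all_ones_gives_zero(self, rng):
        ov = overall_potential(self._pot(np.ones((2, 5)), rng))
        assert np.allclose(ov.values, 0.0)

    def test_floor_forces_minus_four(self, rng):
        ov = overall_potential(self._pot(np.zeros((1, 5)), rng))
        assert ov.values[0] == pytest.approx(-4.0)

    def test_hand_mean(self, rng):
        rM = np.array([[1.0, 0.01, 1.0, 1.0, 1.0]])
        ov = overall_potential(self._pot(rM, rng))
        assert ov.values[0] == pytest.approx(-0.4)

    def test_requires_relative_kind(self, rng):
        pot = self._pot(np.ones((1, 5)), rng)
        pot.kind = "absolute"
        with pytest.raises(ValueError):
            overall_potential(pot)


class TestExportPetal:
    def test_long_format_and_round_trip(self, rng, tmp_path):
        rM = np.abs(rng.lognormal(0, 1, size=(2, 5)))
        pot = TestOverallPotential()._pot(rM, rng)
        path = tmp_path / "petal.csv"
        df = export_petal(pot, path)
        assert len(df) == 10
        back = pd.read_csv(path)
        assert np.allclose(back["potential"].values, df["potential"].values)
        assert ((back["penetrance"] >= 0) & (back["penetrance"] <= 1)).all()
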