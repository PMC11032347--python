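"""Descriptor blocks, conservation laws and the processing pipeline."""

import numpy as np
import pandas as pd
import pytest

from ppi_pocketome import (
    DESCRIPTOR_COLUMNS,
    aggregate_descriptors,
    conditional_log_rescale,
    describe_cavity,
    filter_zero_columns,
    geometric_descriptors,
    process_descriptor_matrix,
    standardize,
    volsite_descriptors,
)
from ppi_pocketome.io_formats import BURIAL_BIN_LABELS
from ppi_pocketome.models import PROBE_TYPES, Cavity, GridPoint

from conftest import random_cavity


def _uniform_cavity(n=30, probe="CA", burial=120):
    points = [GridPoint(coords=np.array([float(i), 0.0, float(i % 5)]),
                        buriedness=burial, probe=probe) for i in range(n)]
    return Cavity("CAVITY_N1", points)


def test_degenerate_composition_counts():
    block = volsite_descriptors(_uniform_cavity())
    assert block["Volume"] == 30.0
    assert block["CA"] == 30
    assert block["CA120"] == 30
    others = [c for c in block.index
              if c not in ("Volume", "CA", "CA120")]
    assert (block[others] == 0).all()


def test_probe_and_burial_conservation(rng):
    for _ in range(10):
        cavity = random_cavity(rng, n_points=int(rng.integers(20, 80)))
        block = volsite_descriptors(cavity)
        t = aggregate_descriptors(block)
        n = len(cavity)
        assert sum(block[p] for p in PROBE_TYPES) == n
        bins = [f"{p}{b}" for p in PROBE_TYPES for b in BURIAL_BIN_LABELS]
        assert block[bins].sum() == n
        assert t.sum() == n
        for p in PROBE_TYPES:
            assert sum(block[f"{p}{b}"] for b in BURIAL_BIN_LABELS) == block[p]


def test_every_buriedness_value_falls_in_exactly_one_bin():
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from ppi_pocketome.descriptors import _burial_bin

    @settings(max_examples=121, derandomize=True)
    @given(b=st.integers(min_value=0, max_value=120))
    def check(b):
        label = _burial_bin(b)
        assert label in BURIAL_BIN_LABELS
        if label == "40":
            assert b <= 40
        elif label == "120":
            assert b == 120
        else:
            lo, hi = (int(v) for v in label.split("."))
            assert lo < b <= hi and b != 120

    check()


def test_burial_bins_partition_recount_oracle(rng):
    """Bin counts equal an independent per-point tally."""
    cavity = random_cavity(rng, n_points=60)
    block = volsite_descriptors(cavity)

    def bin_of(b):
        if b == 120:
            return "120"
        if b <= 40:
            return "40"
        lo = 40 + ((b - 41) // 10) * 10
        return f"{lo}.{lo + 10}"

    tally = {}
    for p in cavity.points:
        key = f"{p.probe}{bin_of(p.buriedness)}"
        tally[key] = tally.get(key, 0) + 1
    for key, count in tally.items():
        assert block[key] == count


def test_full_vector_has_109_components(hd_cavity):
    vec = describe_cavity(hd_cavity)
    assert list(vec.index) == list(DESCRIPTOR_COLUMNS)
    assert len(vec) == 109
    assert vec["Volume"] == len(hd_cavity)
    assert not vec.isna().any()


def _brute_force_shape(coords):
    """Textbook formulas, written independently of the implementation."""
    c = coords - coords.mean(axis=0)
    n = len(c)
    inertia = np.zeros((3, 3))
    for r in c:
        inertia += np.dot(r, r) * np.eye(3) - np.outer(r, r)
    pm1, pm2, pm3 = np.sort(np.linalg.eigvalsh(inertia))
    gyr = np.sort(np.linalg.eigvalsh(c.T @ c / n))
    e1, e2, e3 = gyr
    return {
        "PMI1": pm1, "PMI2": pm2, "PMI3": pm3,
        "NPR1": pm1 / pm3, "NPR2": pm2 / pm3,
        "Rgyr": np.sqrt(np.sum(c**2) / n),
        "Asphericity": ((e3 - e2) ** 2 + (e3 - e1) ** 2 + (e2 - e1) ** 2)
        / (2.0 * (e1 + e2 + e3) ** 2),
        "SpherocityIndex": 3.0 * e1 / (e1 + e2 + e3),
        "Eccentricity": np.sqrt(pm3**2 - pm1**2) / pm3,
        "InertialShapeFactor": pm2 / (pm1 * pm3),
    }


def test_geometric_descriptors_match_brute_force(rng):
    for _ in range(5):
        coords = rng.normal(size=(50, 3)) * rng.uniform(0.5, 4.0, size=3)
        got = geometric_descriptors(coords)
        expected = _brute_force_shape(coords)
        for name, value in expected.items():
            assert got[name] == pytest.approx(value, abs=1e-9), name


def test_geometric_descriptors_match_rdkit(rng):
    """Cross-check against the RDKit 3D shape descriptors (unit mass)."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors3D
    from rdkit.Geometry import Point3D

    coords = rng.normal(size=(40, 3)) * np.array([3.0, 1.5, 0.7])
    mol = Chem.RWMol()
    for _ in coords:
        mol.AddAtom(Chem.Atom(6))
    conf = Chem.Conformer(len(coords))
    for i, p in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*p))
    mol.AddConformer(conf)
    m = mol.GetMol()

    got = geometric_descriptors(coords)
    unit_mass = {"PMI1", "PMI2", "PMI3", "NPR1", "NPR2",
                 "InertialShapeFactor"}
    rdkit_names = {"Rgyr": "RadiusOfGyration"}
    for name in got.index:
        fn = getattr(Descriptors3D, rdkit_names.get(name, name))
        ref = fn(m, useAtomicMasses=False) if name in unit_mass else fn(m)
        assert got[name] == pytest.approx(ref, rel=1e-9), name


def test_geometric_block_is_rigid_motion_invariant(rng):
    from scipy.spatial.transform import Rotation

    coords = rng.normal(size=(40, 3)) * np.array([3.0, 1.5, 0.7])
    base = geometric_descriptors(coords)
    rot = Rotation.from_euler("xyz", [15, -40, 120], degrees=True)
    moved = rot.apply(coords) + np.array([10.0, -5.0, 3.0])
    assert np.allclose(geometric_descriptors(moved).values, base.values,
                       atol=1e-9)


def test_symmetric_cloud_has_degenerate_moments():
    # points on a cube lattice: all three moments equal
    g = np.arange(-2, 3, dtype=float)
    coords = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
    vec = geometric_descriptors(coords)
    assert vec["NPR1"] == pytest.approx(1.0, abs=1e-9)
    assert vec["NPR2"] == pytest.approx(1.0, abs=1e-9)
    assert vec["Asphericity"] == pytest.approx(0.0, abs=1e-9)


def test_collinear_cloud_is_rod_like():
    coords = np.column_stack([np.linspace(0, 10, 100),
                              np.zeros(100), np.zeros(100)])
    with pytest.warns(UserWarning, match="collinear"):
        vec = geometric_descriptors(coords)
    assert vec["Eccentricity"] == pytest.approx(1.0, abs=1e-9)
    assert vec["SpherocityIndex"] == pytest.approx(0.0, abs=1e-9)
    assert vec["InertialShapeFactor"] == 0.0


def test_zero_filter_strict_boundary():
    rng = np.random.default_rng(0)
    base = np.abs(rng.normal(size=(100, 3))) + 0.1
    base[:96, 1] = 0.0   # 96% zeros: dropped
    base[:95, 2] = 0.0   # 95% zeros: kept ("more than 95%" is strict)
    table = pd.DataFrame(base, columns=["a", "b", "c"])
    reduced, state = filter_zero_columns(table)
    assert list(reduced.columns) == ["a", "c"]
    assert state.zero_fractions["b"] == pytest.approx(0.96)


def test_zero_filter_requires_surviving_columns():
    table = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
    with pytest.raises(ValueError):
        filter_zero_columns(table)


@pytest.mark.parametrize("values, expect_flag", [
    ([0, 0, 0, 1, 100], False),       # mean 20.2 >= 15% of max
    ([0] * 99 + [100], True),         # mean 1 < 15, median 0 < 0.65
    ([5, 5, 5, 5], False),            # constant: mean equals max
])
def test_conditional_log_rescale_conditions(values, expect_flag):
    col = pd.Series(values, dtype=float, name="x")
    out, flagged = conditional_log_rescale(col)
    assert flagged == expect_flag
    if flagged:
        assert np.allclose(out, np.log1p(col))
    else:
        assert np.allclose(out, col)


def test_standardize_closed_form():
    table = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    out, state = standardize(table)
    expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(3.0 / 2.0)
    assert np.allclose(out["x"], expected, atol=1e-12)
    assert state.means["x"] == pytest.approx(2.0)
    assert state.sds["x"] == pytest.approx(np.sqrt(2.0 / 3.0))


def test_standardize_outputs_zero_mean_unit_variance(rng):
    table = pd.DataFrame(rng.uniform(0, 100, size=(50, 8)))
    table.columns = [f"c{i}" for i in range(8)]
    out, _ = standardize(table)
    assert np.abs(out.mean(axis=0)).max() < 1e-9
    assert np.abs(out.var(axis=0, ddof=0) - 1.0).max() < 1e-9


def test_pipeline_state_projection_is_idempotent(rng):
    table = pd.DataFrame(np.abs(rng.normal(size=(40, 6))) * 10,
                         columns=[f"c{i}" for i in range(6)])
    out, state = process_descriptor_matrix(table)
    again = state.transform(table)
    assert np.allclose(out.values, again.values, atol=1e-12)


def test_pipeline_is_row_permutation_equivariant(rng):
    table = pd.DataFrame(np.abs(rng.normal(size=(30, 5))),
                         columns=[f"c{i}" for i in range(5)],
                         index=[f"p{i}" for i in range(30)])
    out1, _ = process_descriptor_matrix(table)
    perm = rng.permutation(30)
    out2, _ = process_descriptor_matrix(table.iloc[perm])
    assert np.allclose(out1.iloc[perm].values, out2.values, atol=1e-12)
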