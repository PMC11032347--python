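"""The 109-component pocket descriptor vector and its processing pipeline.

Each cavity is summarized by:

* 89 probe/burial descriptors — the pocket volume, the total count of grid
  points per pharmacophoric probe type (CA, CZ, O, OD1, OG, N, NZ, DU),
  and an 8 x 10 table of per-probe counts binned by buriedness ("40" =
  exposed, buriedness <= 40; "x.y" = x < buriedness <= y; "120" = every
  ray blocked);
* 10 aggregate T bins — the burial histogram summed over probe types;
* 10 geometric shape descriptors of the point cloud: principal moments of
  inertia (unit mass, about the centroid), their normalized ratios,
  radius of gyration, asphericity, spherocity index, eccentricity and
  inertial shape factor.

The processing pipeline mirrors common practice for skewed count data:
columns that are zero for more than 95% of pockets are discarded, columns
with a strongly skewed distribution (mean < 15% of the maximum and median
< 65% of the mean) are moved to a log(1+x) scale, and all kept columns
are standardized to zero mean and unit (population) variance.  The fitted
state can be serialized and re-applied to project new pockets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import BURIAL_BIN_LABELS, DESCRIPTOR_COLUMNS, GEOMETRIC_COLUMNS
from .models import PROBE_TYPES, Cavity

__all__ = [
    "volsite_descriptors",
    "aggregate_descriptors",
    "geometric_descriptors",
    "describe_cavity",
    "PipelineState",
    "filter_zero_columns",
    "conditional_log_rescale",
    "standardize",
    "process_descriptor_matrix",
]

logger = logging.getLogger(__name__)

ZERO_FRACTION_CUTOFF = 0.95
LOG_MEAN_MAX_RATIO = 0.15
LOG_MEDIAN_MEAN_RATIO = 0.65


def _burial_bin(b: int) -> str:
    """Bin label for one buriedness value (0..120 ray scale)."""
    if b == 120:
        return "120"
    if b <= 40:
        return "40"
    lo = ((b - 1) // 10) * 10
    return f"{lo}.{lo + 10}"


def volsite_descriptors(cavity: Cavity) -> pd.Series:
    """The 89 probe/burial descriptors of one cavity."""
    values = {"Volume": cavity.volume}
    for p in PROBE_TYPES:
        values[p] = 0
    for p in PROBE_TYPES:
        for b in BURIAL_BIN_LABELS:
            values[f"{p}{b}"] = 0
    for point in cavity.points:
        if point.probe not in PROBE_TYPES:
            raise ValueError(f"unassigned probe on cavity {cavity.cavity_id}")
        values[point.probe] += 1
        values[f"{point.probe}{_burial_bin(point.buriedness)}"] += 1
    cols = ("Volume",) + PROBE_TYPES + tuple(
        f"{p}{b}" for p in PROBE_TYPES for b in BURIAL_BIN_LABELS)
    return pd.Series([float(values[c]) for c in cols], index=cols)


def aggregate_descriptors(block: pd.Series) -> pd.Series:
    """The 10 T bins: burial histogram aggregated over probe types."""
    data = {}
    for b in BURIAL_BIN_LABELS:
        data[f"T{b}"] = float(sum(block[f"{p}{b}"] for p in PROBE_TYPES))
    return pd.Series(data)


def _shape_values(coords: np.ndarray) -> dict[str, float]:
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    # unit-mass inertia tensor about the centroid
    r2 = np.einsum("ij,ij->i", centered, centered)
    inertia = r2.sum() * np.eye(3) - centered.T @ centered
    pm = np.sort(np.linalg.eigvalsh(inertia))
    pm = np.maximum(pm, 0.0)
    # gyration (covariance) tensor eigenvalues
    gyr = np.sort(np.linalg.eigvalsh(centered.T @ centered / n))
    gyr = np.maximum(gyr, 0.0)
    e1, e2, e3 = gyr
    tr = e1 + e2 + e3

    out = {
        "PMI1": pm[0], "PMI2": pm[1], "PMI3": pm[2],
        "NPR1": pm[0] / pm[2] if pm[2] > 0 else 0.0,
        "NPR2": pm[1] / pm[2] if pm[2] > 0 else 0.0,
        "Rgyr": float(np.sqrt(r2.mean())),
        "Asphericity": 0.5 * ((e3 - e2) ** 2 + (e3 - e1) ** 2 + (e2 - e1) ** 2)
        / tr**2 if tr > 0 else 0.0,
        "SpherocityIndex": 3.0 * e1 / tr if tr > 0 else 0.0,
    }
    if pm[2] > 0:
        out["Eccentricity"] = float(np.sqrt(pm[2] ** 2 - pm[0] ** 2) / pm[2])
    else:
        out["Eccentricity"] = 0.0
    if pm[0] > 1e-12 * pm[2]:
        out["InertialShapeFactor"] = pm[1] / (pm[0] * pm[2])
    else:
        # rod-like limit: the smallest moment vanishes
        warnings.warn("degenerate (collinear) cavity geometry; "
                      "InertialShapeFactor set to 0", stacklevel=2)
        out["InertialShapeFactor"] = 0.0
    return out


def geometric_descriptors(cavity: Cavity | np.ndarray) -> pd.Series:
    """The 10 shape descriptors of a cavity point cloud (unit point mass)."""
    coords = cavity.coords() if isinstance(cavity, Cavity) else np.asarray(cavity,
                                                                           float)
    if len(coords) < 4:
        raise ValueError("need at least 4 points for shape descriptors")
    vals = _shape_values(coords)
    return pd.Series([vals[c] for c in GEOMETRIC_COLUMNS],
                     index=list(GEOMETRIC_COLUMNS))


def describe_cavity(cavity: Cavity) -> pd.Series:
    """Full 109-component descriptor vector, in canonical column order."""
    block = volsite_descriptors(cavity)
    t = aggregate_descriptors(block)
    geo = geometric_descriptors(cavity)
    vec = pd.concat([block, t, geo])
    return vec.reindex(list(DESCRIPTOR_COLUMNS))


# ---------------------------------------------------------------------------
# descriptor-processing pipeline


@dataclass
class PipelineState:
    """Fitted processing state, reusable to project new pockets."""

    kept_columns: list[str]
    zero_fractions: dict[str, float]
    log_flags: dict[str, bool] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineState":
        return cls(**json.loads(Path(path).read_text()))

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Project a raw descriptor table through the fitted pipeline."""
        out = table[self.kept_columns].astype(float).copy()
        for col, flagged in self.log_flags.items():
            if flagged:
                if (out[col] < 0).any():
                    raise ValueError(f"negative values in log-scaled column {col}")
                out[col] = np.log1p(out[col])
        for col in out.columns:
            out[col] = (out[col] - self.means[col]) / self.sds[col]
        return out


def filter_zero_columns(
    table: pd.DataFrame,
    cutoff: float = ZERO_FRACTION_CUTOFF,
) -> tuple[pd.DataFrame, PipelineState]:
    """Drop columns that are zero in more than *cutoff* of the rows."""
    if len(table) < 2:
        raise ValueError("need at least 2 pockets")
    fractions = (table == 0).mean(axis=0)
    kept = [c for c in table.columns if fractions[c] <= cutoff]
    if not kept:
        raise ValueError("every descriptor column was dropped by the zero filter")
    state = PipelineState(kept_columns=kept,
                          zero_fractions={c: float(fractions[c])
                                          for c in table.columns})
    return table[kept], state


def conditional_log_rescale(column: pd.Series) -> tuple[pd.Series, bool]:
    """log(1+x) rescale for skewed non-negative columns.

    Applied iff the mean is below 15% of the maximum and the median below
    65% of the mean (both strict).
    """
    x = column.astype(float)
    max_v = float(x.max())
    mean_v = float(x.mean())
    median_v = float(x.median())
    flagged = max_v > 0 and mean_v < LOG_MEAN_MAX_RATIO * max_v \
        and median_v < LOG_MEDIAN_MEAN_RATIO * mean_v
    if flagged:
        if (x < 0).any():
            raise ValueError(f"negative values in column {column.name!r} "
                             "selected for log rescale")
        return np.log1p(x), True
    return x, False


def standardize(
    table: pd.DataFrame,
    state: PipelineState | None = None,
) -> tuple[pd.DataFrame, PipelineState]:
    """Scale every column to zero mean, unit population variance.

    Constant columns cannot be standardized and are dropped with a
    warning.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 pockets to standardize")
    state = state or PipelineState(kept_columns=list(table.columns),
                                   zero_fractions={})
    out = {}
    kept = []
    for col in table.columns:
        x = table[col].astype(float)
        sd = float(x.std(ddof=0))
        if sd == 0:
            logger.warning("dropping constant descriptor column %r", col)
            continue
        mean = float(x.mean())
        state.means[col] = mean
        state.sds[col] = sd
        out[col] = (x - mean) / sd
        kept.append(col)
    if not kept:
        raise ValueError("no non-constant descriptor columns")
    state.kept_columns = kept
    return pd.DataFrame(out, index=table.index), state


def process_descriptor_matrix(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, PipelineState]:
    """Full pipeline: zero filter, conditional log rescale, standardize."""
    reduced, state = filter_zero_columns(table)
    rescaled = {}
    for col in reduced.columns:
        x = reduced[col].astype(float)
        if (x >= 0).all():
            values, flagged = conditional_log_rescale(x)
        else:
            # the skew rule is defined for count-like non-negative columns
            values, flagged = x, False
        state.log_flags[col] = flagged
        rescaled[col] = values
    out, state = standardize(pd.DataFrame(rescaled, index=reduced.index), state)
    state.log_flags = {c: state.log_flags[c] for c in state.kept_columns}
    return out, state
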