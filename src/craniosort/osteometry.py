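"""Linear osteometry of the atlanto-occipital joint.

The joint is measured with 16 linear distances: eight on the inferior
aspect of the occipital bone (the condylar region, ``*_OC``) and eight on
the superior aspect of the atlas (``*_C1``).  Each occipital distance has a
mechanically corresponding atlas distance (e.g. maximum width of the right
occipital condyle vs. maximum width of the right superior articular facet),
so the 16 raw values reduce to 8 paired differences plus a ninth "overall
size" feature, the difference of the Euclidean norms of the two 8-vectors.

This module provides the per-individual measurement record, measurement
reliability via the technical error of measurement (TEM), the 9-feature
extraction, and the exhaustive cranium x atlas pairwise dataset used to
train match/mismatch classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OC_MEASUREMENTS",
    "C1_MEASUREMENTS",
    "MEASUREMENT_PAIRINGS",
    "FEATURE_NAMES",
    "MeasurementSet",
    "TEMResult",
    "compute_tem",
    "extract_features",
    "build_pairwise_dataset",
    "measurements_to_frame",
]

#: Occipital-side measurement codes, in canonical order.
OC_MEASUREMENTS = ("AR_OC", "AL_OC", "CR_OC", "CL_OC", "E_OC", "G_OC", "I_OC", "K_OC")

#: Atlas-side measurement codes, ordered so that position i corresponds
#: mechanically to ``OC_MEASUREMENTS[i]``.
C1_MEASUREMENTS = ("BRS_C1", "BLS_C1", "DRS_C1", "DLS_C1", "F_C1", "H_C1", "J_C1", "L_C1")

#: The 8 occipital/atlas measurement pairings (condyle width R/L, condyle
#: length R/L, foramen magnum AP/ML vs vertebral foramen AP/ML, lateral
#: span, medial separation).
MEASUREMENT_PAIRINGS = tuple(zip(OC_MEASUREMENTS, C1_MEASUREMENTS))

#: Feature columns of the pairwise dataset: 8 paired differences + norm diff.
FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 10))

VALID_SEX = ("female", "male", "unknown")


@dataclass(frozen=True)
class MeasurementSet:
    """One individual's 16 linear distances (mm).

    Parameters
    ----------
    individual_id : str
        Opaque identifier; unique within a sample.
    oc : dict
        The 8 occipital distances keyed by :data:`OC_MEASUREMENTS`.
    c1 : dict
        The 8 atlas distances keyed by :data:`C1_MEASUREMENTS`.
    sex : {"female", "male", "unknown"}
    """

    individual_id: str
    oc: dict[str, float]
    c1: dict[str, float]
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEX:
            raise ValueError(f"sex must be one of {VALID_SEX}, got {self.sex!r}")
        for keys, values, side in ((OC_MEASUREMENTS, self.oc, "oc"), (C1_MEASUREMENTS, self.c1, "c1")):
            missing = set(keys) - set(values)
            if missing:
                raise ValueError(f"{side} side of {self.individual_id!r} missing {sorted(missing)}")
            extra = set(values) - set(keys)
            if extra:
                raise ValueError(f"{side} side of {self.individual_id!r} has unknown keys {sorted(extra)}")
            for k in keys:
                v = float(values[k])
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(
                        f"measurement {k} of {self.individual_id!r} must be finite and positive, got {v}"
                    )

    def oc_vector(self) -> np.ndarray:
        """Occipital distances as an 8-vector in canonical order (mm)."""
        return np.array([self.oc[k] for k in OC_MEASUREMENTS], dtype=float)

    def c1_vector(self) -> np.ndarray:
        """Atlas distances as an 8-vector in pairing order (mm)."""
        return np.array([self.c1[k] for k in C1_MEASUREMENTS], dtype=float)


@dataclass(frozen=True)
class TEMResult:
    """Technical error of measurement between two repeated series.

    ``tem`` is the absolute error in mm (Dahlberg form), ``rtem`` the error
    relative to the grand mean in percent, and ``acceptable`` whether
    ``rtem`` falls at or below the acceptability threshold used for
    anthropometric repeatability studies (default 7.5%).
    """

    tem: float
    rtem: float
    acceptable: bool
    threshold: float = 7.5


def compute_tem(
    series_a: Sequence[float],
    series_b: Sequence[float],
    acceptability_threshold: float = 7.5,
) -> TEMResult:
    """Intra/inter-observer agreement between two series of repeated measurements.

    Uses the Dahlberg absolute TEM, ``sqrt(sum(d_i^2) / (2 N))`` over the
    paired differences ``d_i = a_i - b_i``, and the relative TEM
    ``100 * TEM / mean`` where the mean is taken over all ``2 N`` values.

    Parameters
    ----------
    series_a, series_b : sequence of float
        Paired repeated measurements (same items, same order), mm.
    acceptability_threshold : float
        Maximum acceptable rTEM in percent.

    Returns
    -------
    TEMResult
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("measurement series must be one-dimensional")
    if a.size != b.size:
        raise ValueError(f"series lengths differ: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("measurement series are empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("measurement series contain non-finite values")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("measurements must be strictly positive")
    d = a - b
    tem = float(np.sqrt(np.sum(d * d) / (2.0 * a.size)))
    grand_mean = float(np.mean(np.concatenate([a, b])))
    rtem = 100.0 * tem / grand_mean
    return TEMResult(tem=tem, rtem=rtem, acceptable=rtem <= acceptability_threshold,
                     threshold=acceptability_threshold)


def _norm(v: np.ndarray, squared: bool) -> float:
    ss = float(np.dot(v, v))
    return ss if squared else float(np.sqrt(ss))


def extract_features(oc_source: MeasurementSet, c1_source: MeasurementSet,
                     squared_norm: bool = False) -> np.ndarray:
    """Nine-feature vector for one cranium x atlas pairing.

    Features 1-8 are the paired differences ``m_OC,i - m_C1,i`` over the 8
    measurement pairings; feature 9 is the difference of the Euclidean norms
    of the occipital and atlas 8-vectors.  The occipital side of
    ``oc_source`` is paired with the atlas side of ``c1_source``, so the two
    arguments may come from different individuals.

    Parameters
    ----------
    oc_source : MeasurementSet
        Supplies the occipital (cranium) side.
    c1_source : MeasurementSet
        Supplies the atlas side.
    squared_norm : bool
        If True, feature 9 uses the squared norm (sum of squares) instead of
        the Euclidean norm.  Off by default; the Euclidean form is the one
        whose scale matches the observed feature-9 statistics.

    Returns
    -------
    numpy.ndarray, shape (9,)
    """
    oc = oc_source.oc_vector()
    c1 = c1_source.c1_vector()
    f = np.empty(9, dtype=float)
    f[:8] = oc - c1
    f[8] = _norm(oc, squared_norm) - _norm(c1, squared_norm)
    return f


def build_pairwise_dataset(individuals: Iterable[MeasurementSet],
                           squared_norm: bool = False) -> pd.DataFrame:
    """Exhaustive cranium x atlas pairing table.

    Every occipital side is paired with every atlas side, giving ``n**2``
    rows for ``n`` individuals, of which exactly ``n`` (the diagonal,
    ``oc_id == c1_id``) are labelled ``correspondent`` and the rest
    ``non-correspondent``.  This is the working dataset for the pairwise
    match/mismatch classifiers: with n = 150 it holds 22,500 rows of which
    150 are correspondent.

    Returns
    -------
    pandas.DataFrame
        Columns ``oc_id, c1_id, f1..f9, label``.
    """
    people = list(individuals)
    if len(people) == 0:
        raise ValueError("need at least one individual")
    ids = [p.individual_id for p in people]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate individual ids: {dupes}")

    n = len(people)
    oc_mat = np.stack([p.oc_vector() for p in people])            # (n, 8)
    c1_mat = np.stack([p.c1_vector() for p in people])            # (n, 8)
    oc_norm = np.array([_norm(v, squared_norm) for v in oc_mat])
    c1_norm = np.array([_norm(v, squared_norm) for v in c1_mat])

    # broadcast: row block i holds OC of individual i against every C1
    feats = oc_mat[:, None, :] - c1_mat[None, :, :]               # (n, n, 8)
    f9 = oc_norm[:, None] - c1_norm[None, :]                      # (n, n)
    oc_idx, c1_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")

    frame = pd.DataFrame(feats.reshape(n * n, 8), columns=list(FEATURE_NAMES[:8]))
    frame["f9"] = f9.ravel()
    frame.insert(0, "oc_id", [ids[i] for i in oc_idx.ravel()])
    frame.insert(1, "c1_id", [ids[j] for j in c1_idx.ravel()])
    frame["label"] = np.where(oc_idx.ravel() == c1_idx.ravel(),
                              "correspondent", "non-correspondent")
    return frame


def measurements_to_frame(individuals: Iterable[MeasurementSet]) -> pd.DataFrame:
    """Tabulate measurement sets as one row per individual (CSV schema order)."""
    rows = []
    for p in individuals:
        row: dict[str, object] = {"individual_id": p.individual_id, "sex": p.sex}
        row.update({k: p.oc[k] for k in OC_MEASUREMENTS})
        row.update({k: p.c1[k] for k in C1_MEASUREMENTS})
        rows.append(row)
    return pd.DataFrame(rows)
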