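"""Resting-state-network label transfer by nearest-centroid matching.

Canonical 7-network labels (visual, somatomotor, dorsal attention, salience,
limbic, control, default mode) live on a labelled source parcellation; each
target region inherits the label of its Euclidean-nearest source node.
Subcortical/brainstem regions are labelled ``SUBCORT`` and excluded from
RSN-level analyses downstream.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ContractError, ParameterError

RSN_NAMES = ("VIS", "SM", "DAT", "SAL", "LIM", "CNT", "DMN")
SUBCORT = "SUBCORT"

__all__ = ["RSN_NAMES", "SUBCORT", "assign_rsn", "synthetic_atlas"]


def assign_rsn(
    target: pd.DataFrame,
    source: pd.DataFrame,
    source_labels: pd.Series | dict,
    subcortical_ids: Iterable[str] = (),
) -> pd.Series:
    """Transfer RSN labels to a target parcellation by nearest source node.

    Parameters
    ----------
    target, source : DataFrame
        Centroid tables indexed by region id with columns ``x, y, z`` (mm),
        both in the same coordinate space.
    source_labels : Series or dict
        RSN label per source region id.
    subcortical_ids : iterable of str
        Target ids to label ``SUBCORT`` instead of matching.

    Ties at exactly equal distance resolve to the lowest source row index,
    so the assignment is deterministic.
    """
    if len(source) == 0:
        raise ParameterError("source centroid table is empty")
    labels = pd.Series(source_labels)
    missing = source.index.difference(labels.index)
    if len(missing):
        raise ContractError(f"source regions without labels: {list(missing)[:5]}")
    coords_t = target[["x", "y", "z"]].to_numpy(dtype=float)
    coords_s = source.loc[:, ["x", "y", "z"]].to_numpy(dtype=float)
    if not (np.all(np.isfinite(coords_t)) and np.all(np.isfinite(coords_s))):
        raise ContractError("centroid coordinates must be finite")
    nearest = cdist(coords_t, coords_s).argmin(axis=1)  # argmin → lowest index on ties
    out = pd.Series(
        labels.iloc[nearest].to_numpy(), index=target.index, name="rsn", dtype=object
    )
    subcortical_ids = set(subcortical_ids)
    out[out.index.isin(subcortical_ids)] = SUBCORT
    return out


def synthetic_atlas(
    n_source: int = 70,
    rng: np.random.Generator | int | None = 0,
    extent_mm: float = 70.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """A synthetic labelled source parcellation for tests and demos.

    Source nodes are placed uniformly in a cube of half-width ``extent_mm``
    and assigned the 7 canonical RSN labels in blocks; this stands in for a
    real high-resolution labelled atlas, which tests must not download.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    coords = rng.uniform(-extent_mm, extent_mm, size=(n_source, 3))
    ids = [f"SRC{i:04d}" for i in range(n_source)]
    table = pd.DataFrame(coords, columns=["x", "y", "z"], index=pd.Index(ids, name="region_id"))
    labels = pd.Series(
        [RSN_NAMES[i * len(RSN_NAMES) // n_source] for i in range(n_source)],
        index=table.index,
        name="rsn",
    )
    return table, labels
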