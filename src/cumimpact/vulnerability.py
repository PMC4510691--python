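"""Habitat x stressor vulnerability weight matrix and its derivation rules.

The weights mu_ij express how strongly stressor j degrades habitat i; they
multiply the normalized stressor intensities in the impact model. Three
derivation rules adapt a generic weight set to the stressor layers actually
mapped:

* demersal nondestructive **low-bycatch** fishing weights are 0.75 times the
  corresponding high-bycatch weights;
* **nutrient input** weights are the arithmetic mean of the oligotrophic and
  eutrophic water-quality weights;
* **sea-level-rise** weights are set to zero for deep benthic and pelagic
  habitats, where shoreline inundation is meaningless.

All derivations are pure (they return a new matrix), idempotent, and touch
only their target column; every derived cell is tagged in the provenance
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VulnerabilityMatrix",
    "load_weights",
    "save_weights",
    "derive_low_bycatch",
    "derive_nutrient",
    "zero_slr_deep",
    "apply_default_derivations",
]

PROVENANCE_TAGS = ("given", "derived_lowbycatch", "derived_nutrient", "zeroed_slr")


@dataclass
class VulnerabilityMatrix:
    """Non-negative weights indexed by habitat (rows) and stressor (columns).

    ``weights`` is a float DataFrame; ``provenance`` is a same-shaped
    DataFrame of tags recording how each cell was obtained.
    """

    weights: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.weights
        if w.index.has_duplicates:
            raise ValueError(f"duplicate habitat ids: {sorted(w.index[w.index.duplicated()])}")
        if w.columns.has_duplicates:
            raise ValueError(f"duplicate stressor ids: {sorted(w.columns[w.columns.duplicated()])}")
        if w.isna().any().any():
            cell = w.stack(future_stack=True)
            missing = cell[cell.isna()].index[0]
            raise ValueError(f"missing weight for (habitat, stressor) = {missing}")
        if (w.to_numpy() < 0).any():
            arr = w.to_numpy()
            i, j = np.unravel_index(int(np.argmin(arr)), arr.shape)
            raise ValueError(
                f"negative weight {arr[i, j]} for habitat {w.index[i]!r}, stressor {w.columns[j]!r}"
            )
        if self.provenance.shape != w.shape:
            raise ValueError("provenance shape must match weights shape")

    # -- construction --------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        habitat_ids: Sequence[str],
        stressor_ids: Sequence[str],
        weights: np.ndarray,
    ) -> "VulnerabilityMatrix":
        w = pd.DataFrame(np.asarray(weights, dtype=float), index=list(habitat_ids), columns=list(stressor_ids))
        prov = pd.DataFrame("given", index=w.index, columns=w.columns)
        return cls(w, prov)

    # -- accessors ------------------------------------------------------

    @property
    def habitat_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def stressor_ids(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def weight(self, habitat_id: str, stressor_id: str) -> float:
        return float(self.weights.at[habitat_id, stressor_id])

    def column(self, stressor_id: str) -> pd.Series:
        if stressor_id not in self.weights.columns:
            raise KeyError(f"unknown stressor column {stressor_id!r}")
        return self.weights[stressor_id]

    def subset(self, habitat_ids: Sequence[str] | None = None, stressor_ids: Sequence[str] | None = None) -> "VulnerabilityMatrix":
        h = list(habitat_ids) if habitat_ids is not None else self.habitat_ids
        s = list(stressor_ids) if stressor_ids is not None else self.stressor_ids
        missing_h = set(h) - set(self.habitat_ids)
        missing_s = set(s) - set(self.stressor_ids)
        if missing_h:
            raise KeyError(f"unknown habitat ids: {sorted(missing_h)}")
        if missing_s:
            raise KeyError(f"unknown stressor ids: {sorted(missing_s)}")
        return VulnerabilityMatrix(self.weights.loc[h, s].copy(), self.provenance.loc[h, s].copy())

    def copy(self) -> "VulnerabilityMatrix":
        return VulnerabilityMatrix(self.weights.copy(), self.provenance.copy())

    def equals(self, other: "VulnerabilityMatrix") -> bool:
        return self.weights.equals(other.weights)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_weights(path: str | Path) -> VulnerabilityMatrix:
    """Load a weight CSV: first column ``habitat_id``, remaining columns stressor ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"weight file not found: {path}")
    df = pd.read_csv(path)
    if df.columns[0] != "habitat_id":
        raise ValueError(f"first CSV column must be 'habitat_id', got {df.columns[0]!r}")
    df = df.set_index("habitat_id")
    df = df.apply(pd.to_numeric)
    prov = pd.DataFrame("given", index=df.index, columns=df.columns)
    return VulnerabilityMatrix(df.astype(float), prov)


def save_weights(matrix: VulnerabilityMatrix, path: str | Path) -> None:
    matrix.weights.rename_axis("habitat_id").to_csv(path)


# ---------------------------------------------------------------------------
# Derivation rules
# ---------------------------------------------------------------------------


def derive_low_bycatch(
    matrix: VulnerabilityMatrix,
    high_col: str = "demersal_nondestructive_high_bycatch",
    low_col: str = "demersal_nondestructive_low_bycatch",
) -> VulnerabilityMatrix:
    """Set ``low_col`` = 0.75 x ``high_col`` for every habitat."""
    if high_col not in matrix.weights.columns:
        raise KeyError(f"unknown high-bycatch column {high_col!r}")
    out = matrix.copy()
    out.weights[low_col] = 0.75 * out.weights[high_col]
    out.provenance[low_col] = "derived_lowbycatch"
    return out


def derive_nutrient(
    matrix: VulnerabilityMatrix,
    oligo_col: str = "nutrient_oligotrophic",
    eutro_col: str = "nutrient_eutrophic",
    out_col: str = "nutrient_input",
) -> VulnerabilityMatrix:
    """Set ``out_col`` to the per-habitat mean of the oligotrophic and eutrophic columns."""
    for c in (oligo_col, eutro_col):
        if c not in matrix.weights.columns:
            raise KeyError(f"unknown nutrient source column {c!r}")
    out = matrix.copy()
    out.weights[out_col] = 0.5 * (out.weights[oligo_col] + out.weights[eutro_col])
    out.provenance[out_col] = "derived_nutrient"
    return out


def zero_slr_deep(
    matrix: VulnerabilityMatrix,
    slr_col: str = "sea_level_rise",
    deep_habitats: Iterable[str] = (),
) -> tuple[VulnerabilityMatrix, int]:
    """Zero the sea-level-rise weights of the given deep habitats.

    Returns the new matrix and the count of cells actually changed (cells
    already zero do not count).
    """
    if slr_col not in matrix.weights.columns:
        raise KeyError(f"unknown sea-level-rise column {slr_col!r}")
    deep = list(deep_habitats)
    unknown = set(deep) - set(matrix.habitat_ids)
    if unknown:
        raise KeyError(f"unknown habitat ids: {sorted(unknown)}")
    out = matrix.copy()
    prior = out.weights.loc[deep, slr_col]
    n_changed = int((prior != 0).sum())
    out.weights.loc[deep, slr_col] = 0.0
    out.provenance.loc[deep, slr_col] = "zeroed_slr"
    return out, n_changed


def apply_default_derivations(
    matrix: VulnerabilityMatrix,
    stressor_ids: Sequence[str] | None = None,
    deep_habitats: Iterable[str] | None = None,
) -> VulnerabilityMatrix:
    """Run the standard derivation pipeline and drop auxiliary source columns.

    Applies, in order: low-bycatch scaling (when the high-bycatch column is
    present), nutrient averaging (when both source columns are present) and
    sea-level-rise zeroing for the deep-habitat set (default: the package's
    deep benthic and pelagic registry classes). When ``stressor_ids`` is
    given the result is restricted to those columns, in that order.
    """
    from .synthetic import DEEP_HABITATS, NUTRIENT_SOURCE_COLS

    out = matrix
    if "demersal_nondestructive_high_bycatch" in out.weights.columns:
        out = derive_low_bycatch(out)
    if all(c in out.weights.columns for c in NUTRIENT_SOURCE_COLS):
        out = derive_nutrient(out)
    if "sea_level_rise" in out.weights.columns:
        deep = [h for h in (deep_habitats if deep_habitats is not None else DEEP_HABITATS) if h in out.habitat_ids]
        out, _ = zero_slr_deep(out, deep_habitats=deep)
    if stressor_ids is None:
        stressor_ids = [c for c in out.stressor_ids if c not in NUTRIENT_SOURCE_COLS]
    return out.subset(stressor_ids=stressor_ids)
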