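"""Core data containers and plain-text I/O.

A :class:`LipidMatrix` holds a samples x lipid-species abundance matrix
together with the missingness mask, the lipid-class annotation, and the
scale the values are currently on.  The clinical covariate table is a plain
:class:`pandas.DataFrame` indexed by sample id (one row per sample, one
column per covariate, including the binary case/control ``status`` column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Valid scale states, in the only order transitions may occur.
SCALE_STATES = ("raw", "log", "log-median-normalized")


@dataclass
class LipidMatrix:
    """Samples x lipid species abundance matrix with annotations.

    Parameters
    ----------
    values
        DataFrame of abundances, rows = samples, columns = lipid species.
        Missing entries are ``NaN``.
    lipid_classes
        Series mapping each lipid id to its lipid class (e.g. ``"PC"``).
    missing_mask
        Boolean DataFrame, same shape as ``values``; ``True`` marks cells
        that were missing in the raw data (kept for audit even after
        imputation).  Defaults to ``values.isna()``.
    scale_state
        One of ``"raw"``, ``"log"``, ``"log-median-normalized"``.
    """

    values: pd.DataFrame
    lipid_classes: pd.Series
    missing_mask: pd.DataFrame = None
    scale_state: str = "raw"
    log_base: float | None = None

    def __post_init__(self) -> None:
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if not self.values.columns.is_unique:
            raise ValueError("lipid ids must be unique")
        if self.scale_state not in SCALE_STATES:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        missing_ann = [c for c in self.values.columns if c not in self.lipid_classes.index]
        if missing_ann:
            raise ValueError(f"lipids without class annotation: {missing_ann[:5]}")

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def lipid_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_lipids(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale_state: str | None = None,
                    log_base: float | None = None) -> "LipidMatrix":
        """Return a copy with new values, checking the scale transition."""
        new_state = self.scale_state if scale_state is None else scale_state
        old_i = SCALE_STATES.index(self.scale_state)
        new_i = SCALE_STATES.index(new_state)
        if new_i < old_i:
            raise ValueError(
                f"illegal scale transition {self.scale_state!r} -> {new_state!r}")
        return replace(self, values=values, scale_state=new_state,
                       log_base=self.log_base if log_base is None else log_base)

    def subset_samples(self, sample_ids) -> "LipidMatrix":
        return replace(self, values=self.values.loc[sample_ids],
                       missing_mask=self.missing_mask.loc[sample_ids])

    def subset_lipids(self, lipid_ids) -> "LipidMatrix":
        return replace(self, values=self.values[list(lipid_ids)],
                       missing_mask=self.missing_mask[list(lipid_ids)],
                       lipid_classes=self.lipid_classes.loc[list(lipid_ids)])


# ---------------------------------------------------------------------------
# Plain-text I/O.  All artifacts are TSV (missing = empty field) or JSON.
# ---------------------------------------------------------------------------

def write_lipid_matrix(matrix: LipidMatrix, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.abundance.tsv``, ``<prefix>.annotation.tsv`` and
    ``<prefix>.mask.tsv``; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": prefix.with_suffix(".abundance.tsv"),
        "annotation": prefix.with_suffix(".annotation.tsv"),
        "mask": prefix.with_suffix(".mask.tsv"),
    }
    matrix.values.to_csv(paths["abundance"], sep="\t", na_rep="")
    ann = matrix.lipid_classes.rename("lipid_class").rename_axis("lipid")
    ann.to_frame().to_csv(paths["annotation"], sep="\t")
    matrix.missing_mask.astype(int).to_csv(paths["mask"], sep="\t")
    return paths


def read_lipid_matrix(prefix: str | Path, scale_state: str = "raw") -> LipidMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".abundance.tsv"), sep="\t", index_col=0)
    ann = pd.read_csv(prefix.with_suffix(".annotation.tsv"), sep="\t", index_col=0)
    mask_path = prefix.with_suffix(".mask.tsv")
    mask = None
    if mask_path.exists():
        mask = pd.read_csv(mask_path, sep="\t", index_col=0).astype(bool)
    return LipidMatrix(values=values, lipid_classes=ann["lipid_class"],
                       missing_mask=mask, scale_state=scale_state)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clinical.rename_axis("sample").to_csv(path, sep="\t")
    return path


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
    return path
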