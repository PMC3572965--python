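"""The five lesion descriptors consumed by the pattern tree.

For each subject: the total white-matter-lesion volume (ml) and the four
relative regional volumes, WMLr = 100 x region / total (%).  Relative volumes
decouple lesion *location* from lesion *load*, so a split on a WMLr descriptor
asks "where are the lesions" rather than "how many".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .cohort import CohortValidationError, RegionalVolumes, Subject

__all__ = ["FEATURE_NAMES", "WmlFeatures", "compute_wmlr", "feature_frame", "write_features", "read_features"]

#: Descriptor order; also the tie-breaking priority used by the tree.
FEATURE_NAMES = ("total_wml", "frontal_wmlr", "parietal_wmlr", "temporal_wmlr", "occipital_wmlr")


@dataclass(frozen=True)
class WmlFeatures:
    """Total WML volume (ml) plus the four relative regional volumes (%)."""

    total_wml: float
    frontal_wmlr: float
    parietal_wmlr: float
    temporal_wmlr: float
    occipital_wmlr: float
    zero_total: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def compute_wmlr(volumes: RegionalVolumes) -> WmlFeatures:
    """Relative regional volumes: 100 x region / total for each of the four lobes.

    A subject with zero total lesion volume has no defined lesion geography;
    all WMLr are set to 0 and ``zero_total`` flags the case for audit (such a
    subject sits below any total-volume split and never reaches a WMLr node).
    """
    if volumes.total == 0:
        return WmlFeatures(0.0, 0.0, 0.0, 0.0, 0.0, zero_total=True)
    t = volumes.total
    return WmlFeatures(
        total_wml=t,
        frontal_wmlr=100.0 * volumes.frontal / t,
        parietal_wmlr=100.0 * volumes.parietal / t,
        temporal_wmlr=100.0 * volumes.temporal / t,
        occipital_wmlr=100.0 * volumes.occipital / t,
    )


def feature_frame(subjects: Iterable[Subject]) -> pd.DataFrame:
    """Descriptor table: one row per subject, subject_id index, 5 descriptor columns."""
    rows = {}
    for s in subjects:
        f = compute_wmlr(s.wml)
        rows[s.subject_id] = f.as_dict() | {"zero_total": f.zero_total}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=list(FEATURE_NAMES) + ["zero_total"])
    df.index.name = "subject_id"
    return df


def write_features(df: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    df.to_csv(path)
    return path


def read_features(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing descriptor columns {missing}")
    return df
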