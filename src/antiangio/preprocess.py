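"""Robust quartile normalization of feature matrices.

Each feature x is rescaled to y = (x - median(X)) / (Q3(X) - Q1(X)), with the
quartiles computed on the *training* matrix only (linear-interpolation
quantile convention).  After transforming the training matrix every
non-degenerate feature has median 0 and interquartile range 1.  Features with
zero IQR fall back to a divisor of 1 (centering only) so matrix widths stay
stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["QuartileScaler", "fit_quartile_scaler"]


@dataclass
class QuartileScaler:
    feature_names: tuple[str, ...]
    median_: np.ndarray
    q1_: np.ndarray
    q3_: np.ndarray
    fallback_: np.ndarray  # True where IQR == 0 (divisor forced to 1)

    @property
    def scale_(self) -> np.ndarray:
        iqr = self.q3_ - self.q1_
        return np.where(self.fallback_, 1.0, iqr)

    @classmethod
    def fit(cls, train: pd.DataFrame) -> "QuartileScaler":
        if len(train) < 2:
            raise ValueError("quartile scaler requires at least 2 samples")
        X = train.to_numpy(float)
        q1, med, q3 = np.quantile(X, [0.25, 0.5, 0.75], axis=0, method="linear")
        return cls(tuple(train.columns), med, q1, q3, (q3 - q1) == 0)

    def transform(self, m: pd.DataFrame) -> pd.DataFrame:
        mismatch = set(m.columns) ^ set(self.feature_names)
        if mismatch:
            raise ValueError(f"feature names do not match scaler: {sorted(mismatch)[:5]}")
        X = m[list(self.feature_names)].to_numpy(float)
        out = pd.DataFrame((X - self.median_) / self.scale_,
                           index=m.index, columns=self.feature_names)
        out.attrs.update(m.attrs)
        return out

    # --- serialization (structured text) ---------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("feature\tmedian\tq1\tq3\tfallback\n")
            for i, name in enumerate(self.feature_names):
                fh.write(f"{name}\t{float(self.median_[i])!r}\t{float(self.q1_[i])!r}"
                         f"\t{float(self.q3_[i])!r}\t{int(self.fallback_[i])}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QuartileScaler":
        names, med, q1, q3, fb = [], [], [], [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                n, m, a, b, f = line.rstrip("\n").split("\t")
                names.append(n)
                med.append(float(m)); q1.append(float(a)); q3.append(float(b))
                fb.append(bool(int(f)))
        return cls(tuple(names), np.array(med), np.array(q1), np.array(q3),
                   np.array(fb))


def fit_quartile_scaler(train: pd.DataFrame) -> QuartileScaler:
    """Fit per-feature median/Q1/Q3 on the training matrix (leakage-safe)."""
    return QuartileScaler.fit(train)
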