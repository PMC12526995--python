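"""Leave-one-subject-out (LOSO) evaluation.

For each subject in turn, the estimator is fitted on every other subject's
cycles and scored (RMSE, cm) on the held-out subject, grouped by radar
position.  No cycle of the held-out subject enters training or validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .cnn import CnnSpec, TrainConfig, build_cnn, evaluate_cnn, train_cnn
from .polyreg import fit_polyreg
from .stats import rmse, summarize


class CycleEstimator(Protocol):
    def fit(self, cycles: pd.DataFrame) -> None: ...

    def predict(self, cycles: pd.DataFrame) -> np.ndarray: ...


@dataclass
class EvalTable:
    """Per-subject RMSE rows plus the summary statistics per case."""

    rows: pd.DataFrame  # index subject, one column per case
    summary: pd.DataFrame  # index mean/std/ci95, one column per case

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def grand_mean(self) -> float:
        return float(self.rows.to_numpy().mean())


def _summarize_rows(rows: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in rows.columns:
        mean, std, hw = summarize(rows[col].to_numpy())
        out[col] = [mean, std, hw]
    return pd.DataFrame(out, index=["mean", "std", "ci95"])


class PolyregEstimator:
    """Depth from per-cycle peak Doppler via polynomial regression."""

    def __init__(self, order: int = 2, feature: str = "peak_doppler_hz") -> None:
        self.order = order
        self.feature = feature
        self.model = None

    def fit(self, cycles: pd.DataFrame) -> None:
        self.model = fit_polyreg(
            cycles[self.feature], cycles["depth_ref_cm"], order=self.order
        )

    def predict(self, cycles: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.model.predict(cycles[self.feature]))


class CnnEstimator:
    """Depth from single-cycle spectrogram crops via the CNN regressor."""

    def __init__(
        self,
        spec: CnnSpec | None = None,
        train_config: TrainConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.spec = spec or CnnSpec()
        self.train_config = train_config or TrainConfig(seed=seed)
        self.model = None
        self.history = None

    @staticmethod
    def _stack(cycles: pd.DataFrame) -> np.ndarray:
        return np.stack(cycles["image"].to_list())

    def fit(self, cycles: pd.DataFrame) -> None:
        self.model = build_cnn(self.spec, seed=self.train_config.seed)
        self.history = train_cnn(
            self.model,
            self._stack(cycles),
            cycles["depth_ref_cm"].to_numpy(),
            self.train_config,
        )

    def predict(self, cycles: pd.DataFrame) -> np.ndarray:
        return self.model.predict(self._stack(cycles))

    def score(self, cycles: pd.DataFrame) -> float:
        return evaluate_cnn(
            self.model, self._stack(cycles), cycles["depth_ref_cm"].to_numpy()
        )


def loso_evaluate(
    cycles: pd.DataFrame,
    estimator_factory: Callable[[], CycleEstimator],
    case_col: str = "case",
) -> EvalTable:
    """Leave-one-subject-out RMSE table.

    ``cycles`` must carry ``subject``, ``depth_ref_cm`` and the estimator's
    inputs.  Training pools all of the remaining subjects' cycles; RMSE is
    reported per (held-out subject, case).
    """
    subjects = sorted(cycles["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    cases = sorted(cycles[case_col].unique())
    rows = {}
    for subj in subjects:
        test = cycles[cycles["subject"] == subj]
        if test.empty:
            raise ValueError(f"subject {subj} has no cycles")
        train = cycles[cycles["subject"] != subj]
        est = estimator_factory()
        est.fit(train)
        pred = est.predict(test)
        row = {}
        for case in cases:
            m = (test[case_col] == case).to_numpy()
            if m.any():
                row[f"case{case}"] = rmse(pred[m], test.loc[m, "depth_ref_cm"])
            else:
                row[f"case{case}"] = np.nan
        rows[subj] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "subject"
    return EvalTable(rows=table, summary=_summarize_rows(table.dropna(axis=1)))


def integration_eval(cycles: pd.DataFrame, case_col: str = "case") -> EvalTable:
    """Per-(subject, case) RMSE of the training-free integration estimates."""
    rows = {}
    for subj, sub in cycles.groupby("subject"):
        rows[subj] = {
            f"case{case}": rmse(g["depth_cm"], g["depth_ref_cm"])
            for case, g in sub.groupby(case_col)
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "subject"
    return EvalTable(rows=table, summary=_summarize_rows(table.dropna(axis=1)))
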