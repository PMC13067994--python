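"""Long-format container and file I/O for intensive-longitudinal (EMA) data.

One row per respondent-by-occasion observation: a respondent identifier, an
occasion index, a timestamp in hours since study start, J ordinal item
responses coded 0..G (missing allowed), and optional covariate columns.
Respondents may differ in their number of occasions. Between-occasion
intervals are always recomputed from the timestamps, never read from file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


@dataclass
class Schema:
    """Column-name mapping for :func:`read_dataset`.

    ``one_based_categories`` declares input coded 1..G+1; responses are
    shifted to the internal 0..G coding on read.
    """

    id_col: str = "id"
    occasion_col: str = "occasion"
    time_col: str = "time_hours"
    item_cols: list[str] | None = None
    covariate_cols: list[str] = field(default_factory=list)
    one_based_categories: bool = False


@dataclass
class EMADataset:
    """Validated long-format EMA dataset.

    Attributes
    ----------
    respondent_id : (n,) array of respondent labels, one per observation row.
    occasion_index : (n,) int array, starting at 1 within each respondent.
    time_hours : (n,) float array, strictly increasing within respondent.
    responses : (n, J) float array; codes 0..G with NaN marking missing.
    covariates : (n, U) float array (U may be 0).
    covariate_names : list of U column names.
    n_categories : G + 1.
    intervals : (n,) float array of within-respondent time differences
        delta_t = time_t - time_{t-1}; NaN on each respondent's first row.
    """

    respondent_id: np.ndarray
    occasion_index: np.ndarray
    time_hours: np.ndarray
    responses: np.ndarray
    n_categories: int
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    intervals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.respondent_id = np.asarray(self.respondent_id)
        self.occasion_index = np.asarray(self.occasion_index, dtype=int)
        self.time_hours = np.asarray(self.time_hours, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.covariates is None:
            self.covariates = np.empty((len(self.responses), 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        self._validate()
        self.intervals = self._compute_intervals()

    def _validate(self) -> None:
        y = self.responses
        if y.ndim != 2:
            raise ValidationError("responses must be an n x J matrix")
        finite = y[~np.isnan(y)]
        if finite.size and (np.any(finite != np.round(finite))
                            or finite.min() < 0
                            or finite.max() > self.n_categories - 1):
            bad = np.argwhere(~np.isnan(y) & ((y < 0) | (y > self.n_categories - 1)
                                              | (y != np.round(y))))
            r, c = bad[0]
            raise ValidationError(
                f"response out of range 0..{self.n_categories - 1} "
                f"at row {r}, item column {c} (value {y[r, c]})"
            )
        for rid in self.respondent_ids:
            t = self.time_hours[self.respondent_id == rid]
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"timestamps not strictly increasing for respondent {rid!r}"
                )

    def _compute_intervals(self) -> np.ndarray:
        delta = np.full(len(self.time_hours), np.nan)
        for rid in self.respondent_ids:
            idx = np.flatnonzero(self.respondent_id == rid)
            delta[idx[1:]] = np.diff(self.time_hours[idx])
        return delta

    @property
    def respondent_ids(self) -> np.ndarray:
        _, order = np.unique(self.respondent_id, return_index=True)
        return self.respondent_id[np.sort(order)]

    @property
    def n_observations(self) -> int:
        return self.responses.shape[0]

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def respondent_slices(self) -> list[np.ndarray]:
        """Row indices per respondent, in first-appearance order."""
        return [np.flatnonzero(self.respondent_id == rid)
                for rid in self.respondent_ids]

    def to_frame(self) -> pd.DataFrame:
        J = self.n_items
        df = pd.DataFrame({
            "id": self.respondent_id,
            "occasion": self.occasion_index,
            "time_hours": self.time_hours,
        })
        for j in range(J):
            df[f"item_{j + 1}"] = self.responses[:, j]
        for u, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, u]
        return df


def read_dataset(path, schema: Schema | None = None,
                 n_categories: int | None = None) -> EMADataset:
    """Read a delimited long-format file into a validated :class:`EMADataset`.

    Rows are sorted by respondent (first-appearance order) then time. Item
    columns default to every column named ``item_*``. Missing responses may
    be empty cells or the string ``NA``. ``n_categories`` defaults to
    1 + the maximum observed code.
    """
    schema = schema or Schema()
    df = pd.read_csv(path, na_values=["NA", ""])
    item_cols = schema.item_cols or [c for c in df.columns if c.startswith("item_")]
    if not item_cols:
        raise ValidationError("no item columns found")
    for col in (schema.id_col, schema.occasion_col, schema.time_col):
        if col not in df.columns:
            raise ValidationError(f"required column {col!r} missing")
    df = df.sort_values([schema.id_col, schema.time_col], kind="stable")
    y = df[item_cols].to_numpy(dtype=float)
    if schema.one_based_categories:
        y = y - 1
    if n_categories is None:
        n_categories = int(np.nanmax(y)) + 1
    return EMADataset(
        respondent_id=df[schema.id_col].to_numpy(),
        occasion_index=df[schema.occasion_col].to_numpy(dtype=int),
        time_hours=df[schema.time_col].to_numpy(dtype=float),
        responses=y,
        n_categories=n_categories,
        covariates=df[schema.covariate_cols].to_numpy(dtype=float)
        if schema.covariate_cols else None,
        covariate_names=list(schema.covariate_cols),
    )


def write_dataset(dataset: EMADataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result artifacts
# ---------------------------------------------------------------------------

def _attentive_table(model) -> pd.DataFrame:
    rows = []
    thr = model.thresholds
    load = model.loading_matrix()
    for j in range(model.n_items):
        row = {"item": j + 1}
        for m in range(load.shape[1]):
            row[f"loading_{m + 1}"] = load[j, m]
        for g in range(thr.shape[1]):
            row[f"kappa_{g + 1}"] = thr[j, g]
        rows.append(row)
    return pd.DataFrame(rows)


def _cier_table(model) -> pd.DataFrame:
    row = {"pref_var": model.pref_var}
    for g, k in enumerate(model.thresholds):
        row[f"kappa_{g + 1}"] = k
    return pd.DataFrame([row])


def write_results(fit, path, posteriors: np.ndarray | None = None,
                  metadata: dict | None = None) -> dict:
    """Serialise a fitted mixture to flat tabular + structured-text files.

    Writes ``attentive_params.csv``, ``cier_params.csv``, ``mixture.json``
    and, when per-observation posteriors are supplied, ``posteriors.csv``
    (one row per observation). Returns the mapping of artifact names to
    paths. Raises on an empty/unfitted object rather than writing stubs.
    """
    if fit is None or getattr(fit, "attentive", None) is None:
        raise ValueError("refusing to serialise an empty fit")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["attentive"] = out / "attentive_params.csv"
    _attentive_table(fit.attentive).to_csv(paths["attentive"], index=False)
    paths["cier"] = out / "cier_params.csv"
    _cier_table(fit.cier).to_csv(paths["cier"], index=False)
    info = {
        "pi_cier": fit.pi_cier,
        "loglik": fit.loglik,
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "best_start": int(fit.best_start),
        "n_best_replicated": int(fit.n_best_replicated),
        "flags": list(getattr(fit, "flags", [])),
    }
    if getattr(fit, "loglik_trace", None) is not None:
        info["loglik_trace"] = [round(float(v), 6) for v in fit.loglik_trace]
    if metadata:
        info["metadata"] = metadata
    paths["mixture"] = out / "mixture.json"
    with open(paths["mixture"], "w") as fh:
        json.dump(info, fh, indent=1)
    if posteriors is not None:
        paths["posteriors"] = out / "posteriors.csv"
        pd.DataFrame(posteriors, columns=["p_attentive", "p_cier"]).to_csv(
            paths["posteriors"], index=False)
    return paths


def read_results(path) -> dict:
    """Read back artifacts written by :func:`write_results`."""
    out = Path(path)
    result = {}
    with open(out / "mixture.json") as fh:
        result["mixture"] = json.load(fh)
    result["attentive"] = pd.read_csv(out / "attentive_params.csv")
    result["cier"] = pd.read_csv(out / "cier_params.csv")
    post = out / "posteriors.csv"
    if post.exists():
        result["posteriors"] = pd.read_csv(post)
    return result


__all__ = [
    "EMADataset",
    "Schema",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "write_results",
    "read_results",
]
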