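"""Covariate encoding for the transition model design matrix.

Each raw covariate is declared as one of

* ``continuous``: centred and scaled by its season-wide mean/sd (constants
  stored for back-transformation, or preset explicitly so that simulated
  truth stays exactly comparable),
* ``cyclic(period)``: encoded as the sine/cosine pair
  ``sin(2 pi c / period), cos(2 pi c / period)``,
* ``categorical(reference)``: dummy columns against the declared reference
  level (e.g. landcover reference "bare_ground", light reference
  "daylight", year reference the first season-year).

The encoder is a scikit-learn transformer; its output always carries a
leading intercept column, matching what the transition model expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["CovariateSpec", "DesignEncoder", "CandidateBlock", "candidate_blocks"]


@dataclass
class CovariateSpec:
    """Declaration of one covariate's encoding.

    kind : {"continuous", "cyclic", "categorical"}
    period : float, required for cyclic covariates (hours, days, degrees...)
    reference : str, required for categorical covariates
    center, scale : optional preset standardisation constants for
        continuous covariates; when absent they are estimated at fit time
    levels : optional explicit level order for categorical covariates
        (reference excluded levels get one dummy column each)
    """

    kind: str
    period: float | None = None
    reference: str | None = None
    center: float | None = None
    scale: float | None = None
    levels: list[str] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "cyclic", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "cyclic":
            if self.period is None or self.period <= 0:
                raise ValueError("cyclic covariates need a positive period")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError("categorical covariates need a reference level")

    @classmethod
    def from_dict(cls, d) -> "CovariateSpec":
        if isinstance(d, CovariateSpec):
            return d
        if isinstance(d, str):
            return cls(kind=d)
        return cls(
            kind=d["kind"],
            period=d.get("period"),
            reference=d.get("reference"),
            center=d.get("center"),
            scale=d.get("scale"),
            levels=d.get("levels"),
        )


class DesignEncoder(TransformerMixin, BaseEstimator):
    """Build transition design matrices from a covariate DataFrame.

    Parameters
    ----------
    spec : dict of covariate name -> CovariateSpec (or its dict/str form)
    add_intercept : bool, default True

    Attributes (after ``fit``)
    --------------------------
    center_, scale_ : per-continuous-covariate standardisation constants
    levels_ : per-categorical-covariate non-reference levels
    feature_names_out_ : encoded column names, intercept first
    """

    def __init__(self, spec: dict, add_intercept: bool = True):
        self.spec = spec
        self.add_intercept = add_intercept

    def _specs(self) -> dict[str, CovariateSpec]:
        return {k: CovariateSpec.from_dict(v) for k, v in self.spec.items()}

    def fit(self, X: pd.DataFrame, y=None):
        specs = self._specs()
        missing = [c for c in specs if c not in X.columns]
        if missing:
            raise ValueError(f"covariates missing from data: {missing}")
        self.center_ = {}
        self.scale_ = {}
        self.levels_ = {}
        names = ["intercept"] if self.add_intercept else []
        for name, sp in specs.items():
            if sp.kind == "continuous":
                v = pd.to_numeric(X[name], errors="coerce")
                center = sp.center if sp.center is not None else float(np.nanmean(v))
                scale = sp.scale if sp.scale is not None else float(np.nanstd(v))
                if not np.isfinite(scale) or scale == 0:
                    raise ValueError(f"covariate {name!r} has zero variance")
                self.center_[name] = center
                self.scale_[name] = scale
                names.append(name)
            elif sp.kind == "cyclic":
                names += [f"{name}_sin", f"{name}_cos"]
            else:
                observed = [str(u) for u in pd.unique(X[name].dropna())]
                levels = sp.levels if sp.levels is not None else sorted(observed)
                if sp.reference not in levels:
                    levels = [sp.reference] + [l for l in levels if l != sp.reference]
                non_ref = [l for l in levels if l != sp.reference]
                self.levels_[name] = non_ref
                names += [f"{name}_{l}" for l in non_ref]
        self.feature_names_out_ = names
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            raise RuntimeError("encoder is not fitted")
        specs = self._specs()
        cols = []
        n = len(X)
        if self.add_intercept:
            cols.append(np.ones(n))
        for name, sp in specs.items():
            if sp.kind == "continuous":
                v = pd.to_numeric(X[name], errors="coerce").to_numpy(float)
                cols.append((v - self.center_[name]) / self.scale_[name])
            elif sp.kind == "cyclic":
                v = pd.to_numeric(X[name], errors="coerce").to_numpy(float)
                w = 2.0 * np.pi * v / sp.period
                cols.append(np.sin(w))
                cols.append(np.cos(w))
            else:
                vals = X[name].astype(str).to_numpy()
                known = set(self.levels_[name]) | {sp.reference}
                unknown = set(vals[pd.notna(X[name]).to_numpy()]) - known
                if unknown:
                    raise ValueError(
                        f"unknown level(s) {sorted(unknown)} for covariate {name!r}"
                    )
                for lev in self.levels_[name]:
                    cols.append((vals == lev).astype(float))
        return np.column_stack(cols)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)

    def inverse_scale(self, name: str, standardised) -> np.ndarray:
        """Map a standardised continuous covariate back to its raw scale."""
        return np.asarray(standardised, float) * self.scale_[name] + self.center_[name]


@dataclass
class CandidateBlock:
    """A named group of design columns entering selection together.

    A cyclic covariate contributes its sin/cos pair, a categorical one its
    dummy set, a continuous one a single column.
    """

    name: str
    columns: list[str] = field(default_factory=list)


def candidate_blocks(encoder: DesignEncoder, names: list[str] | None = None):
    """Candidate blocks for forward selection, one per covariate."""
    specs = encoder._specs()
    out = []
    for name, sp in specs.items():
        if names is not None and name not in names:
            continue
        if sp.kind == "continuous":
            cols = [name]
        elif sp.kind == "cyclic":
            cols = [f"{name}_sin", f"{name}_cos"]
        else:
            cols = [f"{name}_{l}" for l in encoder.levels_[name]]
        out.append(CandidateBlock(name=name, columns=cols))
    seen: set[str] = set()
    for b in out:
        overlap = seen & set(b.columns)
        if overlap:
            raise ValueError(f"blocks share design columns: {sorted(overlap)}")
        seen |= set(b.columns)
    return out
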