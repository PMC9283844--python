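"""Cell-type and tumor-fraction deconvolution from CpG methylation.

An observed plasma methylome Y (per-probe beta values) is modelled as a
non-negative mixture of reference methylomes X (a probes x cell-types beta
atlas): coefficients solve ``argmin_b ||X b - Y||_2`` subject to ``b >= 0``,
and reported fractions are the coefficients normalised to sum to one.

Two flavours are provided: the full multi-cell-type deconvolution on
marker-CpG unions, and a two-component (target tissue vs healthy blood)
deconvolution whose lung fraction is ``b1 / (b1 + b2)``.  Bulk tumor
reference methylomes can first be corrected for non-cancer contamination via
the mixing equation ``M_m = M_c * purity + M_l * (1 - purity)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .stats import bh_adjust, welch_t_test

#: Below this number of shared probes a two-component fit is refused.
MIN_SHARED_PROBES = 10
#: Smallest per-sample probe count observed in practice; fits below it warn.
LOW_PROBE_WARN = 330


@dataclass
class ReferenceAtlas:
    """Reference methylation atlas: probes x cell-type components.

    ``betas`` is a DataFrame indexed by probe_id with one column per
    component; entries are beta values in [0, 1], NaN where missing.
    """

    betas: pd.DataFrame

    def __post_init__(self) -> None:
        if self.betas.index.duplicated().any():
            raise ValueError("duplicate probe_ids in atlas")
        if self.betas.columns.duplicated().any():
            raise ValueError("duplicate component names in atlas")
        vals = self.betas.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("atlas betas outside [0, 1]")
        all_missing = self.betas.isna().all(axis=1)
        if all_missing.any():
            self.betas = self.betas.loc[~all_missing]

    @property
    def component_names(self) -> list[str]:
        return list(self.betas.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.betas.index)

    @classmethod
    def from_csv(cls, path) -> "ReferenceAtlas":
        """Read the MethAtlas CSV dialect: first column probe_id, header of
        component names, empty cell = missing."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.astype(float))

    def to_csv(self, path) -> None:
        self.betas.to_csv(path)


@dataclass(frozen=True)
class MarkerSet:
    target_component: str
    hyper_probes: tuple[str, ...]
    hypo_probes: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.hyper_probes) & set(self.hypo_probes):
            raise ValueError("hyper and hypo marker sets overlap")

    @property
    def all_probes(self) -> tuple[str, ...]:
        return self.hyper_probes + self.hypo_probes


@dataclass
class DeconvResult:
    """Raw NNLS coefficients plus simplex-normalised fractions."""

    coefficients: pd.Series
    fractions: pd.Series
    n_probes_used: int
    residual_norm: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.coefficients, "fraction": self.fractions}
        ).sort_values("fraction", ascending=False)


@dataclass(frozen=True)
class TwoComponentRefs:
    """Per-probe mean betas for a target tissue (x1) and healthy plasma (x2)."""

    probe_ids: tuple[str, ...]
    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.probe_ids) == len(self.x1) == len(self.x2)):
            raise ValueError("probe_ids, x1, x2 must have the same length")


def select_markers(atlas: ReferenceAtlas, target: str, n_each: int = 1000) -> MarkerSet:
    """Select one-vs-rest marker probes for one component.

    Probes are ranked by the margin ``beta_target - mean(beta_others)``:
    descending for hypermethylated markers, ascending for hypomethylated
    ones; ties break lexicographically on probe_id.  Probes with a missing
    target beta are excluded.
    """
    if target not in atlas.component_names:
        raise ValueError(f"component {target!r} not in atlas")
    betas = atlas.betas
    target_beta = betas[target]
    others = betas.drop(columns=[target])
    margin = target_beta - others.mean(axis=1, skipna=True)
    margin = margin.dropna()
    order = pd.DataFrame({"margin": margin, "probe": margin.index})
    hyper = order.sort_values(["margin", "probe"], ascending=[False, True])
    hyper_probes = tuple(hyper["probe"].head(n_each))
    remaining = order[~order["probe"].isin(hyper_probes)]
    hypo = remaining.sort_values(["margin", "probe"], ascending=[True, True])
    hypo_probes = tuple(hypo["probe"].head(n_each))
    return MarkerSet(target, hyper_probes, hypo_probes)


def nnls_fractions(
    sample_betas: pd.Series, atlas: ReferenceAtlas, marker_union=None
) -> DeconvResult:
    """Full NNLS deconvolution of a sample onto the atlas components.

    The fit is restricted to marker probes with non-missing values in both
    the sample and every atlas column (complete-case).
    """
    betas = atlas.betas
    if marker_union is not None:
        probes = pd.Index(sorted(set(marker_union))).intersection(betas.index)
        betas = betas.loc[probes]
    shared = betas.index.intersection(sample_betas.dropna().index)
    X = betas.loc[shared]
    mask = X.notna().all(axis=1)
    X = X.loc[mask]
    y = sample_betas.loc[X.index].to_numpy(dtype=float)
    n_comp = len(atlas.component_names)
    if len(X) < n_comp:
        raise ValueError(
            f"only {len(X)} usable probes for {n_comp} components; need at least {n_comp}"
        )
    coef, residual = nnls(X.to_numpy(dtype=float), y)
    assert np.all(coef >= 0.0)
    coefficients = pd.Series(coef, index=atlas.component_names)
    total = coefficients.sum()
    if total > 0:
        fractions = coefficients / total
    else:
        warnings.warn("all NNLS coefficients are zero; fractions undefined")
        fractions = pd.Series(np.nan, index=atlas.component_names)
    return DeconvResult(coefficients, fractions, len(X), float(residual))


def group_fractions(fractions: pd.Series, group_map: dict[str, str]) -> pd.Series:
    """Collapse per-cell-type fractions into coarser groups by summation."""
    missing = [c for c in fractions.index if c not in group_map]
    if missing:
        raise ValueError(f"components without a group: {missing}")
    groups = fractions.groupby(fractions.index.map(group_map)).sum()
    return groups


def build_two_component_refs(
    target_betas: pd.DataFrame,
    plasma_betas: pd.DataFrame,
    min_valid: int = 2,
) -> TwoComponentRefs:
    """Average replicate reference methylomes into the two-column system.

    Probes lacking valid (non-NA) values in at least ``min_valid`` samples of
    either reference group are removed before averaging.
    """
    shared = target_betas.index.intersection(plasma_betas.index)
    t = target_betas.loc[shared]
    p = plasma_betas.loc[shared]
    keep = (t.notna().sum(axis=1) >= min_valid) & (p.notna().sum(axis=1) >= min_valid)
    t, p = t.loc[keep], p.loc[keep]
    return TwoComponentRefs(
        tuple(t.index),
        t.mean(axis=1, skipna=True).to_numpy(dtype=float),
        p.mean(axis=1, skipna=True).to_numpy(dtype=float),
    )


def two_component_fraction(
    sample_betas: pd.Series, refs: TwoComponentRefs
) -> float:
    """Estimate the target-tissue fraction of a sample by 2-column NNLS.

    Returns ``b1 / (b1 + b2)``; NaN (with a warning) when both coefficients
    are zero.
    """
    ref = pd.DataFrame({"x1": refs.x1, "x2": refs.x2}, index=list(refs.probe_ids))
    shared = ref.index.intersection(sample_betas.dropna().index)
    if len(shared) < MIN_SHARED_PROBES:
        raise ValueError(
            f"only {len(shared)} shared probes; need at least {MIN_SHARED_PROBES}"
        )
    if len(shared) < LOW_PROBE_WARN:
        warnings.warn(
            f"two-component fit on {len(shared)} probes (< {LOW_PROBE_WARN}); "
            "estimate may be unstable"
        )
    X = ref.loc[shared].to_numpy(dtype=float)
    y = sample_betas.loc[shared].to_numpy(dtype=float)
    coef, _ = nnls(X, y)
    b1, b2 = coef
    if b1 + b2 == 0:
        warnings.warn("both two-component coefficients are zero; fraction undefined")
        return float("nan")
    return float(b1 / (b1 + b2))


def purity_correct(m_m, m_l, purity):
    """Invert the mixing equation for the pure cancer methylation level.

    Solves ``M_m = M_c * purity + M_l * (1 - purity)`` for ``M_c`` and clips
    the result to [0, 1].  Accepts scalars or arrays.
    """
    purity_arr = np.asarray(purity, dtype=float)
    if np.any(purity_arr <= 0):
        raise ValueError("purity must be > 0")
    m_c = (np.asarray(m_m, dtype=float) - np.asarray(m_l, dtype=float) * (1.0 - purity_arr)) / purity_arr
    clipped = np.clip(m_c, 0.0, 1.0)
    return float(clipped) if np.isscalar(m_m) else clipped


def select_differential_cpgs(
    tumor_betas: pd.DataFrame,
    plasma_betas: pd.DataFrame,
    exclusion_set=(),
    fdr_cut: float = 0.001,
    min_delta: float = 0.3,
    min_valid: int = 2,
) -> pd.Index:
    """Select probes separating (purity-corrected) tumors from healthy plasma.

    Per probe a Welch t-test compares the two groups; Benjamini-Hochberg
    q-values are computed across all tested probes and a probe is kept when
    q < ``fdr_cut``, the absolute group-mean difference is at least
    ``min_delta``, and it is not in ``exclusion_set``.
    """
    if tumor_betas.shape[1] == 0 or plasma_betas.shape[1] == 0:
        raise ValueError("both groups must contain samples")
    shared = tumor_betas.index.intersection(plasma_betas.index)
    t = tumor_betas.loc[shared]
    p = plasma_betas.loc[shared]
    testable = (t.notna().sum(axis=1) >= min_valid) & (p.notna().sum(axis=1) >= min_valid)
    t, p = t.loc[testable], p.loc[testable]
    if len(t) == 0:
        return pd.Index([])
    pvals = np.ones(len(t))
    deltas = np.zeros(len(t))
    for i, probe in enumerate(t.index):
        a = t.loc[probe].dropna().to_numpy(dtype=float)
        b = p.loc[probe].dropna().to_numpy(dtype=float)
        deltas[i] = a.mean() - b.mean()
        if a.std() == 0 and b.std() == 0:
            pvals[i] = 1.0 if a.mean() == b.mean() else 0.0
        else:
            pvals[i] = welch_t_test(a, b, "two-sided").p_value
    qvals = bh_adjust(pvals)
    keep = (qvals < fdr_cut) & (np.abs(deltas) >= min_delta)
    selected = t.index[keep]
    return selected.difference(pd.Index(list(exclusion_set)))
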