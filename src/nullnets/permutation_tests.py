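"""Monte-Carlo inference on null ensembles.

Two-tailed p-values use the add-one convention
``p = min(1, 2·min((#{null ≥ obs}+1), (#{null ≤ obs}+1)) / (n+1))``
with ties counting toward both tails, which guarantees p ∈ (0, 1] at
any finite number of permutations.  Direction classifies the observed
value against the central (1−α) empirical interval of the null sample
(type-7 interpolated quantiles, strict inequality at the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import TOPICS, MultilayerNetwork, to_incidence
from .metrics import StatisticValue, phi_from_counts
from .null_models import (
    NullEnsemble,
    default_n_swaps,
    generate_ensemble,
    replicate_seed,
    shuffle_layers_constrained,
    shuffle_layers_free,
)

__all__ = [
    "PermutationTestResult",
    "two_tailed_p",
    "classify_direction",
    "summarize_ensemble",
    "run_structural_comparison",
    "run_cross_network_comparison",
]

DEFAULT_STATISTICS = (
    "in_degree_assortativity",
    "out_degree_assortativity",
    "eccentricity_variance",
)


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: str
    layers: tuple[str, ...]
    null_model: str
    observed: float | None
    null_mean: float | None
    null_sd: float | None
    p_two_tailed: float | None
    direction: str  # above / within / below / undefined
    alpha: float
    n_perm: int
    n_undefined: int
    reason: str | None = None


def two_tailed_p(ensemble: NullEnsemble) -> float | None:
    """Add-one two-tailed Monte-Carlo p-value; None if observed undefined."""
    if not ensemble.observed.defined:
        return None
    obs = ensemble.observed.value
    nulls = ensemble.null_values
    n = len(nulls)
    if n < 1:
        return None
    ge = int(np.count_nonzero(nulls >= obs))
    le = int(np.count_nonzero(nulls <= obs))
    return min(1.0, 2.0 * (min(ge, le) + 1) / (n + 1))


def classify_direction(ensemble: NullEnsemble, alpha: float = 0.05) -> str:
    """Position of the observed value against the central (1−α) null range."""
    if not ensemble.observed.defined:
        return "undefined"
    nulls = ensemble.null_values
    if len(nulls) < 1:
        return "undefined"
    obs = ensemble.observed.value
    lo = float(np.quantile(nulls, alpha / 2))  # type-7 linear interpolation
    hi = float(np.quantile(nulls, 1 - alpha / 2))
    if obs > hi:
        return "above"
    if obs < lo:
        return "below"
    return "within"


def summarize_ensemble(ensemble: NullEnsemble, alpha: float = 0.05) -> PermutationTestResult:
    """Summarize an ensemble into the paper-style inferential row."""
    nulls = ensemble.null_values
    defined = ensemble.observed.defined and len(nulls) > 0
    return PermutationTestResult(
        statistic=ensemble.statistic,
        layers=ensemble.layers,
        null_model=ensemble.null_model,
        observed=ensemble.observed.value,
        null_mean=float(nulls.mean()) if len(nulls) else None,
        null_sd=float(nulls.std(ddof=1)) if len(nulls) > 1 else None,
        p_two_tailed=two_tailed_p(ensemble) if defined else None,
        direction=classify_direction(ensemble, alpha) if defined else "undefined",
        alpha=alpha,
        n_perm=ensemble.n_perm,
        n_undefined=ensemble.n_undefined,
        reason=None if ensemble.observed.defined else ensemble.observed.reason,
    )


def _results_frame(rows: list[PermutationTestResult], n_simultaneous: int) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "layer": ["|".join(r.layers) for r in rows],
            "statistic": [r.statistic for r in rows],
            "null_model": [r.null_model for r in rows],
            "observed": [r.observed for r in rows],
            "null_mean": [r.null_mean for r in rows],
            "null_sd": [r.null_sd for r in rows],
            "p": [r.p_two_tailed for r in rows],
            "direction": [r.direction for r in rows],
            "n_undefined": [r.n_undefined for r in rows],
        }
    )
    df["n_simultaneous_tests"] = n_simultaneous  # no multiplicity correction applied
    return df


def run_structural_comparison(
    m: MultilayerNetwork,
    statistics=DEFAULT_STATISTICS,
    null_models=("edge1", "edge2"),
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    n_swaps: int | None = None,
) -> pd.DataFrame:
    """Compare each layer's structural statistics against edge nulls.

    Produces one row per layer × statistic × null model with observed,
    null mean ± sd, two-tailed p and above/within/below direction; the
    machine-readable analogue of a per-layer null-model figure panel.
    Cross nulls may be included in ``null_models`` to test per-layer
    statistics against layer-shuffled networks as well.
    """
    from .metrics import LAYER_STATISTICS
    from .null_models import (
        _layer_from_incidence_col,
        permute_double_swap,
        permute_out_edges,
    )

    stat_fns = {s: LAYER_STATISTICS[s] for s in statistics}
    rows: list[PermutationTestResult] = []
    inc = (
        to_incidence(m)
        if any(nm in ("cross1", "cross2") for nm in null_models)
        else None
    )
    for topic in TOPICS:
        layer = m.layers[topic]
        observed = {s: fn(layer) for s, fn in stat_fns.items()}
        for nm in null_models:
            # one permutation stream per layer x null model; every
            # statistic is recomputed on the same permuted networks
            values: dict[str, list[float]] = {s: [] for s in statistics}
            undefined = {s: 0 for s in statistics}
            for rep in range(n_perm):
                sub = replicate_seed(seed, nm, topic, rep)
                if nm == "edge1":
                    perm_layer = permute_out_edges(layer, sub)
                elif nm == "edge2":
                    perm_layer = permute_double_swap(layer, n_swaps, sub)
                elif nm == "cross1":
                    perm_layer = _layer_from_incidence_col(
                        shuffle_layers_free(inc, sub), m.roster, topic
                    )
                elif nm == "cross2":
                    perm_layer = _layer_from_incidence_col(
                        shuffle_layers_constrained(inc, n_swaps, sub), m.roster, topic
                    )
                else:
                    raise ValueError(f"unknown null model {nm!r}")
                for s, fn in stat_fns.items():
                    sv = fn(perm_layer)
                    if sv.defined:
                        values[s].append(sv.value)
                    else:
                        undefined[s] += 1
            for s in statistics:
                ens = NullEnsemble(
                    statistic=s,
                    layers=(topic,),
                    null_model=nm,
                    observed=observed[s],
                    null_values=np.asarray(values[s], dtype=np.float64),
                    n_undefined=undefined[s],
                    n_perm=n_perm,
                    seed=seed,
                    n_swaps=n_swaps,
                )
                rows.append(summarize_ensemble(ens, alpha))
    return _results_frame(rows, n_simultaneous=len(rows))


def _incidence_phi_vector(
    matrix: np.ndarray, focal_col: int, other_cols: np.ndarray, n_cells: int
) -> np.ndarray:
    """Phi of the focal incidence column against each other column.

    Dyads absent from the incidence are 0 in every layer, so the
    full-matrix correlation over all n(n−1) ordered cells reduces to
    margin counts of the incidence columns.
    """
    f = matrix[:, focal_col].astype(np.int64)
    others = matrix[:, other_cols].astype(np.int64)
    n11 = f @ others
    r1 = int(f.sum())
    c1 = others.sum(axis=0)
    out = np.empty(len(other_cols))
    for j in range(len(other_cols)):
        phi = phi_from_counts(int(n11[j]), r1, int(c1[j]), n_cells)
        out[j] = np.nan if phi is None else phi
    return out


def run_cross_network_comparison(
    m: MultilayerNetwork,
    focal: str = "T.Bycatch",
    null_models=("cross1", "cross2"),
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    n_swaps: int | None = None,
) -> pd.DataFrame:
    """Dyadic correlation of the focal layer with each other layer vs nulls.

    The observed unfolded correlation between the focal layer and each
    of the 8 other layers is compared with its distribution under the
    free (cross1) and margin-constrained (cross2) layer shuffles; the
    machine-readable analogue of a cross-network correlation figure.
    """
    if focal not in TOPICS:
        raise ValueError(f"unknown focal layer {focal!r}")
    inc = to_incidence(m)
    n = len(m.roster)
    n_cells = n * (n - 1)
    focal_col = TOPICS.index(focal)
    other_cols = np.array([i for i in range(len(TOPICS)) if i != focal_col])
    observed = _incidence_phi_vector(inc.matrix, focal_col, other_cols, n_cells)

    rows: list[PermutationTestResult] = []
    for nm in null_models:
        if nm not in ("cross1", "cross2"):
            raise ValueError("cross-network comparison uses cross1/cross2 only")
        nulls = np.empty((n_perm, len(other_cols)))
        for rep in range(n_perm):
            sub = replicate_seed(seed, nm, focal, rep)
            if nm == "cross1":
                perm = shuffle_layers_free(inc, sub)
            else:
                perm = shuffle_layers_constrained(inc, n_swaps, sub)
            nulls[rep] = _incidence_phi_vector(perm.matrix, focal_col, other_cols, n_cells)
        for j, col in enumerate(other_cols):
            col_nulls = nulls[:, j]
            defined_nulls = col_nulls[~np.isnan(col_nulls)]
            obs_defined = not np.isnan(observed[j])
            sv = (
                StatisticValue("dyadic_correlation", float(observed[j]))
                if obs_defined
                else StatisticValue.undefined(
                    "dyadic_correlation", "a layer is empty or complete"
                )
            )
            ens = NullEnsemble(
                statistic="dyadic_correlation",
                layers=(focal, TOPICS[col]),
                null_model=nm,
                observed=sv,
                null_values=defined_nulls,
                n_undefined=int(np.isnan(col_nulls).sum()),
                n_perm=n_perm,
                seed=seed,
                n_swaps=n_swaps,
            )
            rows.append(summarize_ensemble(ens, alpha))
    return _results_frame(rows, n_simultaneous=len(rows))
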