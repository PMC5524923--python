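"""AICc model selection across growth laws and cohort splits.

AICc = 2k - 2 ln L + 2k(k+1)/(n - k - 1), with k the number of structural
growth-law parameters (latent anchor times and the error variance are
profiled nuisances and not counted) and n the number of measurements in the
split being fitted.  Delta-AICc subtracts the column minimum; the best law
in each split scores 0, ties broken toward the law with fewer parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .growth_models import MODEL_NAMES, MODELS, GrowthModelSpec
from .likelihood import FitConfig, FitResult, TumourSeries, fit_model

__all__ = ["aicc", "column_delta", "AICcTable", "compare_models", "DEFAULT_SPLITS"]

logger = logging.getLogger(__name__)

#: Cohort splits in report order: the full cohort, then by karyotype,
#: facial location and host sex.  Ploidy/location splits drop series whose
#: label is unknown; the all-data split keeps everything.
DEFAULT_SPLITS: Dict[str, Dict[str, str]] = {
    "all": {},
    "diploid": {"ploidy": "diploid"},
    "tetraploid": {"ploidy": "tetraploid"},
    "mucosal": {"location": "mucosal"},
    "dermal": {"location": "dermal"},
    "female": {"sex": "female"},
    "male": {"sex": "male"},
}


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k + 1, got n={n}, k={k}")
    return 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1) / (n - k - 1)


def column_delta(
    aicc_by_model: Dict[str, float], k_by_model: Dict[str, int]
) -> Tuple[Dict[str, float], str]:
    """Delta-AICc within one cohort split.

    Subtracts the column minimum (NaN cells stay NaN); ties at the minimum
    are broken toward the law with fewer parameters, then input order.
    Returns (delta per model, winner name).
    """
    names = list(aicc_by_model)
    finite = [m for m in names if np.isfinite(aicc_by_model[m])]
    if not finite:
        raise ValueError("no finite AICc in column")
    best = min(aicc_by_model[m] for m in finite)
    tied = [m for m in finite if np.isclose(aicc_by_model[m], best)]
    winner = min(tied, key=lambda m: (k_by_model[m], names.index(m)))
    ref = aicc_by_model[winner]
    return {m: aicc_by_model[m] - ref for m in names}, winner


@dataclass
class AICcTable:
    """Delta-AICc per (growth law, cohort split), plus the winning law's
    absolute AICc and the measurement count per split."""

    delta: pd.DataFrame  # rows: model names; columns: split names
    best_aicc: pd.Series  # absolute AICc of the winner per split
    best_model: pd.Series  # winner name per split
    n_obs: pd.Series  # measurements per split
    fits: Dict[str, Dict[str, FitResult]] = field(default_factory=dict, repr=False)

    def to_csv(self, path) -> None:
        self.delta.round(2).to_csv(path, index_label="model")

    def __str__(self) -> str:
        df = self.delta.round(2).copy()
        header = ", ".join(
            f"{c}: {m} (AICc {a:.2f}, n={int(nn)})"
            for c, m, a, nn in zip(
                df.columns, self.best_model, self.best_aicc, self.n_obs
            )
        )
        return f"{df.to_string()}\nbest per split -> {header}"


def compare_models(
    series_set: Sequence[TumourSeries],
    specs: Optional[Sequence[GrowthModelSpec]] = None,
    split_definitions: Optional[Dict[str, Dict[str, str]]] = None,
    config: Optional[FitConfig] = None,
) -> AICcTable:
    """Fit every growth law to every cohort split and tabulate delta-AICc.

    A fit failure in one cell is recorded as missing (NaN), not fatal.
    Splits left degenerate after filtering (too few measurements for AICc
    under the largest law) are skipped with a warning.
    """
    from .io_cli import filter_cohort  # local import: io_cli imports us

    specs = list(specs) if specs is not None else [MODELS[m] for m in MODEL_NAMES]
    split_definitions = split_definitions or DEFAULT_SPLITS
    config = config or FitConfig()

    aicc_cells: Dict[str, Dict[str, float]] = {}
    fits: Dict[str, Dict[str, FitResult]] = {}
    n_obs: Dict[str, int] = {}
    for split_name, criteria in split_definitions.items():
        try:
            subset = filter_cohort(series_set, **criteria)
        except ValueError as exc:
            logger.warning("split %s: %s; skipped", split_name, exc)
            continue
        n = sum(s.n_obs for s in subset)
        max_k = max(s.k for s in specs)
        if n < max_k + 2:
            logger.warning("split %s: only %d measurements; skipped", split_name, n)
            continue
        n_obs[split_name] = n
        aicc_cells[split_name] = {}
        fits[split_name] = {}
        for spec in specs:
            try:
                fit = fit_model(subset, spec, config)
            except Exception as exc:
                logger.warning("split %s, model %s: fit failed (%s)",
                               split_name, spec.name, exc)
                aicc_cells[split_name][spec.name] = np.nan
                continue
            aicc_cells[split_name][spec.name] = fit.aicc
            fits[split_name][spec.name] = fit

    if not aicc_cells:
        raise ValueError("no usable split")

    model_names = [s.name for s in specs]
    abs_table = pd.DataFrame(aicc_cells).reindex(model_names)
    k_by_model = {s.name: s.k for s in specs}

    best_model = {}
    best_aicc = {}
    delta_cols = {}
    for col in abs_table.columns:
        deltas, winner = column_delta(abs_table[col].to_dict(), k_by_model)
        best_model[col] = winner
        best_aicc[col] = abs_table.at[winner, col]
        delta_cols[col] = deltas
    best_model = pd.Series(best_model)
    best_aicc = pd.Series(best_aicc)
    delta = pd.DataFrame(delta_cols).reindex(model_names)

    return AICcTable(
        delta=delta,
        best_aicc=best_aicc,
        best_model=best_model,
        n_obs=pd.Series(n_obs),
        fits=fits,
    )
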