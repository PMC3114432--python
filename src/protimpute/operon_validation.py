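"""Biological validation of predicted protein abundances via operons.

Genes co-transcribed in an operon should show coherent protein levels, so
the coefficient of variation (CV) of molecular-weight-normalized predicted
abundances within an operon should be smaller than that of a random gene
set of the same size. For each operon a permutation null is built by
repeatedly sampling size-matched gene sets without replacement from the
prediction pool (2000 draws by default); PCV is the mean permuted CV and
the percentile score is the fraction of permuted CVs at or below the
observed one.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._seeds import substream
from .operons import OperonSet

__all__ = [
    "ValidationReport",
    "molar_normalize",
    "coefficient_of_variation",
    "permutation_null",
    "percentile_score",
    "validate",
]


@dataclasses.dataclass
class ValidationReport:
    """Per-operon CV/PCV/percentile rows plus the two summary fractions."""

    rows: pd.DataFrame  # operon_id, size, cv, pcv, cv_above_pcv, percentile
    n_permutations: int
    seed: int

    @property
    def fraction_cv_below_pcv(self) -> float:
        return float((self.rows["cv"] < self.rows["pcv"]).mean())

    @property
    def fraction_percentile_below_02(self) -> float:
        return float((self.rows["percentile"] < 0.2).mean())

    def summary(self) -> dict:
        return {
            "n_operons": int(len(self.rows)),
            "fraction_CV_below_PCV": self.fraction_cv_below_pcv,
            "fraction_percentile_below_0.2": self.fraction_percentile_below_02,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.rows.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=1))


def molar_normalize(
    predictions: pd.Series, molecular_weight: pd.Series
) -> pd.Series:
    """Divide linear abundances by molecular weight (Da); genes without a
    positive weight are dropped with a warning."""
    mw = molecular_weight.reindex(predictions.index)
    ok = mw.notna() & (mw > 0)
    if (~ok).any():
        warnings.warn(
            f"dropped {int((~ok).sum())} gene(s) without positive molecular weight",
            stacklevel=2,
        )
    return predictions[ok] / mw[ok]


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def _permuted_cvs(
    pool: np.ndarray, group_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    m = pool.size
    if group_size > m:
        raise ValueError(f"group_size {group_size} exceeds pool size {m}")
    if group_size == m:
        draws = np.tile(pool, (n_perm, 1))
    else:
        # size-matched sampling without replacement, vectorized over draws
        keys = rng.random((n_perm, m))
        idx = np.argpartition(keys, group_size - 1, axis=1)[:, :group_size]
        draws = pool[idx]
    means = draws.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("permuted group with zero mean")
    return draws.std(axis=1, ddof=1) / means


def permutation_null(
    pool,
    group_size: int,
    n_perm: int = 2000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """PCV (mean permuted CV) and the permuted CV list for one group size."""
    pool = np.asarray(pool, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = substream(seed, "permutation-null", group_size)
    cvs = _permuted_cvs(pool, group_size, n_perm, rng)
    return float(cvs.mean()), cvs


def percentile_score(observed_cv: float, permuted_cvs) -> float:
    """Fraction of permuted CVs at or below the observed CV (ties count
    against the operon)."""
    permuted = np.asarray(permuted_cvs, dtype=float)
    if permuted.size == 0:
        raise ValueError("empty permuted CV list")
    return float(np.mean(permuted <= observed_cv))


def validate(
    predictions: pd.Series,
    molecular_weight: pd.Series,
    operons: OperonSet,
    n_perm: int = 2000,
    seed: int = 0,
    normalize: bool = True,
) -> ValidationReport:
    """Per-operon CV vs permutation null over the whole prediction pool.

    ``predictions`` are linear-scale abundances (measured plus imputed) for
    one condition. Each operon's null uses its own seed substream indexed
    by operon id, so reports are reproducible and insensitive to operon
    additions. Operons with fewer than 2 predicted genes are dropped with
    a warning.
    """
    values = (
        molar_normalize(predictions, molecular_weight) if normalize else predictions
    )
    pool = values.to_numpy(dtype=float)
    rows = []
    n_dropped = 0
    for op_id, genes in enumerate(operons.operons):
        present = [g for g in genes if g in values.index]
        if len(present) < 2:
            n_dropped += 1
            continue
        observed = coefficient_of_variation(values[present])
        rng = substream(seed, "operon-null", op_id)
        permuted = _permuted_cvs(pool, len(present), n_perm, rng)
        rows.append(
            {
                "operon_id": op_id,
                "size": len(present),
                "cv": observed,
                "pcv": float(permuted.mean()),
                "cv_above_pcv": observed > permuted.mean(),
                "percentile": float(np.mean(permuted <= observed)),
            }
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} operon(s) with <2 predicted genes", stacklevel=2
        )
    if not rows:
        raise ValueError("no operon with >=2 predicted genes")
    return ValidationReport(
        rows=pd.DataFrame(rows), n_permutations=n_perm, seed=seed
    )
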