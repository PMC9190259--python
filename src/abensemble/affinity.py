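"""Per-antibody metric aggregation and affinity correlation.

ln(K_d), with K_d in nM, is the affinity proxy (Gibbs relation
dG = -RT ln K). Per-antibody metrics are means over the six CDRs
(holo/apo PCA cluster counts, dihedral-state counts, DRES) plus the
interface interaction percentages; correlations are squared Pearson
coefficients with a leave-one-out influence diagnostic that generalizes
ad-hoc single-outlier omission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CDR_NAMES = ("H1", "H2", "H3", "L1", "L2", "L3")
SAMPLING_CLASSES = ("more_apo", "equal", "more_holo")


@dataclass
class AffinityRecord:
    """Measured affinity of one antibody."""

    antibody_id: str
    kd_nM: float | None
    koff: float | None = None

    @property
    def ln_kd(self) -> float | None:
        return None if self.kd_nM is None else ln_affinity(self.kd_nM)

    @property
    def ln_koff(self) -> float | None:
        if self.koff is None:
            return None
        if self.koff <= 0:
            raise ValueError(f"{self.antibody_id}: k_off must be positive")
        return math.log(self.koff)


@dataclass
class CorrelationResult:
    """Squared Pearson correlation with least-squares fit and
    leave-one-out diagnostics."""

    x_name: str
    y_name: str
    n: int
    r_squared: float
    slope: float
    intercept: float
    loo_r_squared: dict[str, float]  # R^2 with that point removed
    max_delta_point: str
    max_delta_r_squared: float


def ln_affinity(kd_nM: float) -> float:
    """Natural log of K_d expressed in nM."""
    if kd_nM is None or kd_nM <= 0:
        raise ValueError("K_d must be positive")
    return math.log(kd_nM)


def read_affinities(path) -> list[AffinityRecord]:
    """Read affinities.csv: antibody_id, kd_nM, optional koff; blank or
    non-positive K_d marks the antibody as affinity-unknown."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        kd = row.get("kd_nM")
        kd = None if pd.isna(kd) or kd <= 0 else float(kd)
        koff = row.get("koff") if "koff" in df.columns else None
        koff = None if koff is None or pd.isna(koff) else float(koff)
        records.append(AffinityRecord(str(row["antibody_id"]), kd, koff))
    return records


def build_metric_table(
    per_antibody_cdr_metrics: dict[str, dict[str, dict[str, float]]],
    interaction_percentages: dict[str, dict[str, float]],
    affinities: list[AffinityRecord],
) -> pd.DataFrame:
    """Assemble the per-antibody metric table.

    ``per_antibody_cdr_metrics[antibody][cdr]`` carries the per-CDR
    values (``holo_pca_clusters``, ``apo_pca_clusters``,
    ``holo_dash_states``, ``apo_dash_states``, ``dres``); exactly the six
    CDRs are required. Antibodies without a K_d stay in the table but are
    excluded from every correlation.
    """
    aff = {a.antibody_id: a for a in affinities}
    rows = []
    for ab_id, cdrs in per_antibody_cdr_metrics.items():
        if set(cdrs) != set(CDR_NAMES):
            raise ValueError(
                f"{ab_id}: expected the six CDRs {CDR_NAMES}, got {sorted(cdrs)}"
            )
        row: dict[str, object] = {"antibody_id": ab_id}
        for metric in ("holo_pca_clusters", "apo_pca_clusters", "holo_dash_states", "apo_dash_states", "dres"):
            vals = [cdrs[c][metric] for c in CDR_NAMES if metric in cdrs[c]]
            if vals:
                row[f"mean_{metric}"] = float(np.mean(vals))
        if "mean_apo_pca_clusters" in row and "mean_holo_pca_clusters" in row:
            row["apo_minus_holo_pca"] = row["mean_apo_pca_clusters"] - row["mean_holo_pca_clusters"]
        if "mean_apo_dash_states" in row and "mean_holo_dash_states" in row:
            row["apo_minus_holo_dash"] = row["mean_apo_dash_states"] - row["mean_holo_dash_states"]
        for key, val in interaction_percentages.get(ab_id, {}).items():
            row[key] = val
        rec = aff.get(ab_id)
        row["kd_nM"] = rec.kd_nM if rec else None
        row["ln_kd"] = rec.ln_kd if rec else None
        row["ln_koff"] = rec.ln_koff if rec and rec.koff else None
        row["has_affinity"] = bool(rec and rec.kd_nM)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("antibody_id").reset_index(drop=True)
    return df


def pearson_r2(
    x: np.ndarray,
    y: np.ndarray,
    labels: list[str] | None = None,
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Squared Pearson correlation with slope/intercept and a
    leave-one-out scan reporting the most influential point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    labels = labels or [str(i) for i in range(n)]
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    loo: dict[str, float] = {}
    best_label, best_delta, best_r2 = labels[0], -1.0, r2
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xi, yi = x[mask], y[mask]
        if np.var(xi) == 0 or np.var(yi) == 0:
            continue
        r2_i = float(stats.pearsonr(xi, yi).statistic ** 2)
        loo[labels[i]] = r2_i
        delta = abs(r2_i - r2)
        if delta > best_delta:
            best_label, best_delta, best_r2 = labels[i], delta, r2_i
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        n=n,
        r_squared=r2,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        loo_r_squared=loo,
        max_delta_point=best_label,
        max_delta_r_squared=best_r2,
    )


def correlate_metrics(
    table: pd.DataFrame,
    x_columns: list[str],
    y_column: str = "ln_kd",
) -> list[CorrelationResult]:
    """Correlate each metric column against an affinity column, excluding
    antibodies with missing values pairwise."""
    results = []
    for col in x_columns:
        if col not in table.columns:
            continue
        sub = table[["antibody_id", col, y_column]].dropna()
        if len(sub) < 3:
            continue
        try:
            results.append(
                pearson_r2(
                    sub[col].to_numpy(),
                    sub[y_column].to_numpy(),
                    labels=sub["antibody_id"].tolist(),
                    x_name=col,
                    y_name=y_column,
                )
            )
        except ValueError:
            # a metric constant across the panel carries no correlation
            continue
    return results


def sampling_class_percentages(
    classifications: list[str], method: str = ""
) -> dict[str, float]:
    """Percentage of CDRs in each apo/holo sampling class; sums to 100."""
    if not classifications:
        raise ValueError("at least one classification is required")
    bad = set(classifications) - set(SAMPLING_CLASSES)
    if bad:
        raise ValueError(f"unknown sampling classes: {sorted(bad)}")
    n = len(classifications)
    out = {
        cls: 100.0 * sum(c == cls for c in classifications) / n
        for cls in SAMPLING_CLASSES
    }
    if method:
        out["method"] = method
    return out
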