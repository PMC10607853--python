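"""Sloan neutral community model: fit, prediction and taxon partitioning.

The model predicts a taxon's occurrence frequency across local
communities from its metacommunity relative abundance p via the beta
distribution with shape ``(N*m*p, N*m*(1-p))`` evaluated above the
detection limit d = 1/N. ``N*m`` is fitted by least squares of observed
frequency on predicted frequency; ``m`` follows by dividing by the mean
sample depth N.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import CommunityTable

NM_BOUNDS = (1e-3, 1e7)


def occurrence_abundance(table: CommunityTable) -> pd.DataFrame:
    """Per-taxon mean relative abundance p and occurrence frequency f."""
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValueError("empty table")
    rel = table.relative_abundance()
    return pd.DataFrame(
        {
            "p": rel.mean(axis=0),
            "f": (table.counts > 0).mean(axis=0),
        },
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    )


def predicted_frequency(p, nm: float, detection_limit: float) -> np.ndarray:
    """P(relative abundance > d) under Beta(nm*p, nm*(1-p))."""
    p = np.asarray(p, dtype=float)
    return stats.beta.sf(detection_limit, nm * p, nm * (1.0 - p))


def predicted_frequency_binomial(p, nm: float, n_reads: float) -> np.ndarray:
    """Exact detection probability under binomial read sampling.

    A taxon with latent relative abundance q ~ Beta(nm*p, nm*(1-p)) is
    detected when at least one of N reads hits it:
    P(detect) = 1 - E[(1-q)^N] = 1 - B(a, b+N) / B(a, b).
    The threshold form ``predicted_frequency`` approximates this with a
    step at d = 1/N, which biases fitted nm upward at moderate depths.
    """
    from scipy.special import betaln

    p = np.asarray(p, dtype=float)
    a = nm * p
    b = nm * (1.0 - p)
    return 1.0 - np.exp(betaln(a, b + n_reads) - betaln(a, b))


def wilson_interval(freq: np.ndarray, n: int, level: float = 0.95):
    """Wilson score interval around a predicted frequency at n samples."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    freq = np.asarray(freq, dtype=float)
    denom = 1.0 + z**2 / n
    center = (freq + z**2 / (2 * n)) / denom
    half = z * np.sqrt(freq * (1 - freq) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


@dataclasses.dataclass
class NeutralFit:
    nm: float  # fitted N*m product
    m: float  # migration rate = nm / N
    r_squared: float  # 1 - SSE/SST; may be negative
    n_reads: float  # mean sample depth N used for d and m
    n_samples: int
    detection_limit: float
    taxa: pd.DataFrame  # per taxon: p, f, predicted, ci_low, ci_high, partition

    @property
    def partition_counts(self) -> dict:
        return self.taxa["partition"].value_counts().to_dict()


def fit_sloan(
    table: CommunityTable,
    detection_limit: float | None = None,
    ci_level: float = 0.95,
    pooled_abundance: bool = False,
    detection: str = "threshold",
) -> NeutralFit:
    """Fit N*m by least squares of occurrence frequency on the neutral
    prediction, then partition taxa against the Wilson 95% CI band.

    Taxa never observed (f = 0) cannot enter occurrence data and are
    excluded. ``pooled_abundance`` switches p from the mean of per-sample
    relative abundances to pooled-count relative abundance. ``detection``
    selects the predicted-frequency form: ``"threshold"`` (beta tail above
    d = 1/N, the conventional choice) or ``"binomial"`` (exact marginal
    detection probability under N binomial reads; unbiased for
    parameter-recovery work).
    """
    of = occurrence_abundance(table)
    if pooled_abundance:
        pooled = table.counts.sum(axis=0)
        of["p"] = pooled / pooled.sum()
    of = of[of["f"] > 0]
    if len(of) < 20:
        raise ValueError("need at least 20 observed taxa to fit")
    if (of["f"] >= 1.0).all():
        raise ValueError("degenerate occurrence data: every taxon in every sample")
    n_reads = float(table.sample_sums.mean())
    return fit_occurrence(
        of["p"].to_numpy(),
        of["f"].to_numpy(),
        n_reads=n_reads,
        n_samples=table.n_samples,
        taxon_ids=of.index,
        detection_limit=detection_limit,
        ci_level=ci_level,
        detection=detection,
    )


def fit_occurrence(
    p: np.ndarray,
    f: np.ndarray,
    n_reads: float,
    n_samples: int,
    taxon_ids=None,
    detection_limit: float | None = None,
    ci_level: float = 0.95,
    detection: str = "threshold",
) -> NeutralFit:
    """Fit N*m directly from (abundance, frequency) pairs."""
    if detection not in ("threshold", "binomial"):
        raise ValueError("detection must be 'threshold' or 'binomial'")
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    d = detection_limit if detection_limit is not None else 1.0 / n_reads

    def predict(nm_value: float) -> np.ndarray:
        if detection == "binomial":
            return predicted_frequency_binomial(p, nm_value, n_reads)
        return predicted_frequency(p, nm_value, d)

    def sse(log_nm: float) -> float:
        pred = predict(np.exp(log_nm))
        return float(((f - pred) ** 2).sum())

    res = optimize.minimize_scalar(
        sse, bounds=(np.log(NM_BOUNDS[0]), np.log(NM_BOUNDS[1])), method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"Sloan fit failed: {res.message}")
    nm = float(np.exp(res.x))
    pred = predict(nm)
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    lo, hi = wilson_interval(pred, n_samples, ci_level)

    if taxon_ids is None:
        taxon_ids = [f"taxon_{i}" for i in range(p.size)]
    taxa = pd.DataFrame({"p": p, "f": f}, index=pd.Index(taxon_ids, name="taxon_id"))
    taxa["predicted"] = pred
    taxa["ci_low"] = lo
    taxa["ci_high"] = hi
    taxa["partition"] = np.where(
        f > hi, "above", np.where(f < lo, "below", "neutral")
    )
    return NeutralFit(
        nm=nm,
        m=nm / n_reads,
        r_squared=r2,
        n_reads=n_reads,
        n_samples=n_samples,
        detection_limit=d,
        taxa=taxa,
    )


def partition_taxa(fit: NeutralFit) -> pd.Series:
    """Per-taxon label: above / neutral / below the neutral prediction."""
    return fit.taxa["partition"]


def fit_by_group(
    table: CommunityTable,
    by=("altitude", "season"),
    min_samples: int = 5,
    **kwargs,
) -> dict:
    """One Sloan fit per metadata group; undersized groups are skipped."""
    import warnings

    out = {}
    for key, samples in table.groups(by).items():
        if len(samples) < min_samples:
            warnings.warn(f"group {key} has < {min_samples} samples; skipped",
                          stacklevel=2)
            continue
        sub = table.subset_samples(samples)
        keep = [t for t, tot in zip(sub.taxon_ids, sub.counts.sum(axis=0)) if tot > 0]
        out[key] = fit_sloan(sub.subset_taxa(keep), **kwargs)
    return out


def summarize_fits(fits: dict) -> pd.DataFrame:
    rows = []
    for key, fit in sorted(fits.items(), key=lambda kv: str(kv[0])):
        counts = fit.partition_counts
        rows.append(
            {
                "group": "_".join(str(k) for k in key) if isinstance(key, tuple) else key,
                "Nm": fit.nm,
                "m": fit.m,
                "R2": fit.r_squared,
                "N": fit.n_reads,
                "n_samples": fit.n_samples,
                "n_above": counts.get("above", 0),
                "n_neutral": counts.get("neutral", 0),
                "n_below": counts.get("below", 0),
            }
        )
    return pd.DataFrame(rows).set_index("group")
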