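"""Parameter sweep and rheological regime classification.

One simulated indentation per (k, gamma, alpha) grid point yields a
pair of fit errors (chi_E, chi_P).  K-means with three clusters on the
standardized features (log chi_E, log chi_P, log chi_E/chi_P) separates
materials whose dwell relaxation is decisively power-law (PL),
decisively exponential (EXP), or transitional (TR).  Per-alpha regime
probabilities are tallied from the labels and smoothed with a Gaussian
KDE; the relaxation exponent beta of PL-classified materials is
summarized per alpha.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from .dynamics import DragLaw, Indenter
from .indentation import IndentationProtocol, run_assay
from .lattice import build_fcc
from .rheofit import ExponentialFit, PowerLawFit, fit_exponential, fit_power_law

__all__ = ["SweepGrid", "RegimeRecord", "run_sweep", "kmeans_label",
           "regime_probability", "beta_vs_alpha", "records_to_frame"]

LABELS = ("PL", "EXP", "TR")


@dataclasses.dataclass
class SweepGrid:
    """Material parameter grid.

    Defaults reproduce the full study: k = 100..1000 step 100,
    gamma = 10..100 step 10, alpha = 0.00..1.00 step 0.05 — 2100
    combinations.
    """

    k_values: tuple = tuple(float(k) for k in range(100, 1001, 100))
    gamma_values: tuple = tuple(float(g) for g in range(10, 101, 10))
    alpha_values: tuple = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 4))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.k_values):
            raise ValueError("spring constants must be > 0")
        if any(g <= 0 for g in self.gamma_values):
            raise ValueError("drag constants must be > 0")
        if any(a < 0 for a in self.alpha_values):
            raise ValueError("drag exponents must be >= 0")

    def __len__(self) -> int:
        return len(self.k_values) * len(self.gamma_values) * len(self.alpha_values)

    def points(self):
        for k in self.k_values:
            for g in self.gamma_values:
                for a in self.alpha_values:
                    yield float(k), float(g), float(a)


@dataclasses.dataclass
class RegimeRecord:
    """Per-material sweep result."""

    k: float
    gamma: float
    alpha: float
    chi_E: float
    chi_P: float
    pl_fit: PowerLawFit | None = None
    exp_fit: ExponentialFit | None = None
    label: str | None = None
    ok: bool = True
    error: str = ""

    @property
    def log_ratio(self) -> float:
        """log10(chi_E / chi_P); positive favors the power-law model."""
        return float(np.log10(self.chi_E / self.chi_P))


def _record_key(k: float, g: float, a: float) -> str:
    return f"k{k:g}_g{g:g}_a{a:.4f}"


def run_sweep(
    grid: SweepGrid,
    H: int = 8,
    sigma_s: float = 11.0,
    ell: float = 1.1,
    protocol: IndentationProtocol | None = None,
    cache_dir: str | Path | None = None,
    verbose: bool = False,
) -> list[RegimeRecord]:
    """One assay + both fits per grid point (unlabeled records).

    Deterministic for a fixed grid and protocol.  With ``cache_dir``
    each record is stored as JSON once computed, and re-running an
    interrupted sweep reuses the cached records.  Individual simulation
    failures yield flagged records (``ok=False``), not a fatal error.
    """
    proto = protocol or IndentationProtocol()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    nets: dict[float, object] = {}
    records: list[RegimeRecord] = []
    for k, g, a in grid.points():
        key = _record_key(k, g, a)
        if cache is not None and (cache / f"{key}.json").exists():
            records.append(_load_record(cache / f"{key}.json"))
            continue
        if k not in nets:
            nets[k] = build_fcc(H, ell=ell, k=k)
        net = nets[k]
        try:
            curve = run_assay(net, Indenter(diameter=sigma_s),
                              DragLaw(gamma=g, alpha=a), proto)
            pl = fit_power_law(curve)
            ex = fit_exponential(curve)
            rec = RegimeRecord(k=k, gamma=g, alpha=a, chi_E=ex.chi,
                               chi_P=pl.chi, pl_fit=pl, exp_fit=ex)
        except (FloatingPointError, ValueError) as e:
            rec = RegimeRecord(k=k, gamma=g, alpha=a, chi_E=np.inf,
                               chi_P=np.inf, ok=False, error=str(e))
        if verbose:
            print(f"{key}: chi_P={rec.chi_P:.3e} chi_E={rec.chi_E:.3e}",
                  flush=True)
        if cache is not None:
            _dump_record(rec, cache / f"{key}.json")
        records.append(rec)
    return records


def _dump_record(rec: RegimeRecord, path: Path) -> None:
    d = dataclasses.asdict(rec)
    for fit_key in ("pl_fit", "exp_fit"):
        if d[fit_key] is not None:
            d[fit_key] = {k: (None if isinstance(v, float) and not np.isfinite(v)
                              else v if not isinstance(v, tuple) else list(v))
                          for k, v in d[fit_key].items()}
    path.write_text(json.dumps(d, default=float))


def _load_record(path: Path) -> RegimeRecord:
    d = json.loads(path.read_text())
    pl = d.pop("pl_fit", None)
    ex = d.pop("exp_fit", None)
    rec = RegimeRecord(**{**d,
                          "chi_E": _inf(d["chi_E"]), "chi_P": _inf(d["chi_P"])})
    if pl is not None:
        pl = {k: (_inf(v) if k == "chi" else v) for k, v in pl.items()}
        pl["window"] = tuple(pl["window"] or (np.nan, np.nan))
        rec.pl_fit = PowerLawFit(**{k: (np.nan if v is None else v)
                                    for k, v in pl.items()})
    if ex is not None:
        ex = {k: (_inf(v) if k == "chi" else v) for k, v in ex.items()}
        ex["window"] = tuple(ex["window"] or (np.nan, np.nan))
        rec.exp_fit = ExponentialFit(**{k: (np.nan if v is None else v)
                                        for k, v in ex.items()})
    return rec


def _inf(v):
    return np.inf if v is None else v


def kmeans_label(records: list[RegimeRecord], seed: int = 0,
                 n_restarts: int = 50) -> list[RegimeRecord]:
    """Assign PL / EXP / TR labels by 3-cluster K-means.

    Features per record: (log10 chi_E, log10 chi_P, log10 chi_E/chi_P),
    standardized.  The cluster whose centroid has the largest mean
    log-ratio (power-law model decisively better) maps to PL, the
    smallest to EXP, the remaining one to TR.  Records with non-finite
    chi values keep label None.
    """
    good = [r for r in records if np.isfinite(r.chi_E) and np.isfinite(r.chi_P)
            and r.chi_E > 0 and r.chi_P > 0]
    if len(good) < 3:
        raise ValueError("need at least 3 records with finite chi values")
    X = np.array([[np.log10(r.chi_E), np.log10(r.chi_P), r.log_ratio]
                  for r in good])
    sd = X.std(axis=0)
    if np.all(sd == 0):
        for r in good:
            r.label = "TR"
        import warnings
        warnings.warn("degenerate features: all records identical; labeled TR")
        return records
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(Z)
    # map clusters by centroid log-ratio contrast
    ratio_means = [X[assign == c, 2].mean() if np.any(assign == c) else -np.inf
                   for c in range(3)]
    order = np.argsort(ratio_means)          # ascending: EXP, TR, PL
    cluster_label = {int(order[0]): "EXP", int(order[1]): "TR",
                     int(order[2]): "PL"}
    for r, c in zip(good, assign):
        r.label = cluster_label[int(c)]
    return records


def regime_probability(records: list[RegimeRecord],
                       k_min: float | None = None,
                       gamma_min: float | None = None) -> dict:
    """P(label | alpha) table plus Gaussian-KDE curves per label.

    Returns ``{"table": DataFrame indexed by alpha with columns
    PL/EXP/TR (rows sum to 1), "kde": {label: callable}, "alpha_grid":
    array}``.  ``k_min``/``gamma_min`` restrict to the stiff/viscous
    regime (e.g. k >= 800, gamma >= 80).
    """
    sel = [r for r in records if r.label in LABELS]
    if k_min is not None:
        sel = [r for r in sel if r.k >= k_min]
    if gamma_min is not None:
        sel = [r for r in sel if r.gamma >= gamma_min]
    if not sel:
        raise ValueError("no labeled records after filtering")
    alphas = sorted({r.alpha for r in sel})
    counts = pd.DataFrame(0, index=alphas, columns=list(LABELS), dtype=float)
    for r in sel:
        counts.loc[r.alpha, r.label] += 1
    table = counts.div(counts.sum(axis=1), axis=0)
    table.index.name = "alpha"
    kde = {}
    for lab in LABELS:
        pts = np.array([r.alpha for r in sel if r.label == lab])
        if pts.size >= 2 and pts.std() > 0:
            kde[lab] = gaussian_kde(pts)    # Silverman bandwidth default
        else:
            kde[lab] = None
    return {"table": table, "kde": kde,
            "alpha_grid": np.linspace(min(alphas), max(alphas), 201),
            "n_records": len(sel)}


def beta_vs_alpha(records: list[RegimeRecord]) -> pd.DataFrame:
    """Per-alpha summary of the fitted relaxation exponent beta.

    Uses PL-labeled records only.  Columns: n, beta_mean, beta_sd,
    beta_values (list).
    """
    pl = [r for r in records if r.label == "PL" and r.pl_fit is not None
          and np.isfinite(r.pl_fit.beta)]
    if not pl:
        import warnings
        warnings.warn("no PL-classified records; beta summary is empty")
        return pd.DataFrame(columns=["n", "beta_mean", "beta_sd", "beta_values"])
    rows = {}
    for r in pl:
        rows.setdefault(r.alpha, []).append(r.pl_fit.beta)
    out = pd.DataFrame(
        {
            "n": {a: len(v) for a, v in rows.items()},
            "beta_mean": {a: float(np.mean(v)) for a, v in rows.items()},
            "beta_sd": {a: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                        for a, v in rows.items()},
            "beta_values": {a: list(v) for a, v in rows.items()},
        }
    ).sort_index()
    out.index.name = "alpha"
    return out


def records_to_frame(records: list[RegimeRecord]) -> pd.DataFrame:
    """Flatten records to the sweep CSV schema."""
    rows = []
    for r in records:
        rows.append({
            "k": r.k, "gamma": r.gamma, "alpha": r.alpha,
            "chi_E": r.chi_E, "chi_P": r.chi_P,
            "E_inf_P": r.pl_fit.E_inf if r.pl_fit else np.nan,
            "beta": r.pl_fit.beta if r.pl_fit else np.nan,
            "E_inf_E": r.exp_fit.E_inf if r.exp_fit else np.nan,
            "dE": r.exp_fit.dE if r.exp_fit else np.nan,
            "tau": r.exp_fit.tau if r.exp_fit else np.nan,
            "label": r.label or "", "ok": r.ok,
        })
    return pd.DataFrame(rows)
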