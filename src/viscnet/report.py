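"""Summary outputs for a labeled sweep."""

from __future__ import annotations

from pathlib import Path

from .classify import beta_vs_alpha, records_to_frame, regime_probability

__all__ = ["report"]


def report(records, out_dir, k_min: float | None = None,
           gamma_min: float | None = None) -> dict:
    """Write the sweep CSV, P(alpha) table, beta-vs-alpha table and a
    text summary of the regime boundaries.  Returns the file paths.

    Deterministic: identical records produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    frame = records_to_frame(records)
    paths["sweep"] = out / "sweep.csv"
    frame.to_csv(paths["sweep"], index=False, float_format="%.10g")

    labeled = [r for r in records if r.label]
    summary_lines = [f"records: {len(records)} (labeled: {len(labeled)})"]
    if labeled:
        prob = regime_probability(records, k_min=k_min, gamma_min=gamma_min)
        table = prob["table"]
        paths["p_alpha"] = out / "p_alpha.csv"
        table.to_csv(paths["p_alpha"], float_format="%.10g")

        beta = beta_vs_alpha(records)
        paths["beta_alpha"] = out / "beta_alpha.csv"
        beta.drop(columns=["beta_values"], errors="ignore").to_csv(
            paths["beta_alpha"], float_format="%.10g")

        pl_alphas = [a for a in table.index if table.loc[a, "PL"] >= 0.5]
        exp_alphas = [a for a in table.index if table.loc[a, "EXP"] >= 0.5]
        if pl_alphas:
            summary_lines.append(
                f"power-law dominant for alpha in [{min(pl_alphas):g}, "
                f"{max(pl_alphas):g}]")
        else:
            summary_lines.append("power-law dominant: none")
        if exp_alphas:
            summary_lines.append(
                "exponential dominant for alpha in "
                f"{{{', '.join(f'{a:g}' for a in exp_alphas)}}}")
        if len(beta):
            summary_lines.append(
                "mean beta over PL records: "
                f"{beta['beta_mean'].min():.3f}..{beta['beta_mean'].max():.3f}")
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(summary_lines) + "\n")
    return paths
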