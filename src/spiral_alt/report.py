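"""Human-readable rendering of fitted results.

Numbers are serialized at full double precision in JSON artifacts; the text
tables round to two decimals for display only.
"""

from __future__ import annotations

import io

from .alt import LadderReport
from .mlm import MLMResult

__all__ = ["render_mlm_table", "render_ladder", "write_report"]


def render_mlm_table(result: MLMResult) -> str:
    """Fixed-effects table (b, SE, t, p) and random-intercept row
    (b, SE, z, p) in the conventional layout."""
    buf = io.StringIO()
    buf.write("Fixed effects\n")
    buf.write(f"{'':24s}{'B (SE)':>16s}{'t':>8s}{'p':>8s}\n")
    labels = {
        "intercept": "Intercept",
        "time": "Time (pre vs. post)",
        "condition": "Condition (MBCT vs. WL)",
        "condition_x_time": "Condition X Time",
    }
    for term, row in result.fixed.iterrows():
        b_se = f"{row['estimate']:.2f} ({row['se']:.2f})"
        buf.write(f"{labels.get(term, term):24s}{b_se:>16s}{row['t']:>8.2f}{_fmt_p(row['p']):>8s}\n")
    buf.write("\nRandom effects\n")
    buf.write(f"{'':24s}{'B (SE)':>16s}{'z':>8s}{'p':>8s}\n")
    b_se = f"{result.sigma_u2:.2f} ({result.sigma_u2_se:.2f})"
    buf.write(f"{'Intercept':24s}{b_se:>16s}{result.sigma_u2_z:>8.2f}{_fmt_p(result.sigma_u2_p):>8s}\n")
    buf.write(f"\nAR(1) rho = {result.rho:.2f}; residual variance = {result.sigma_e2:.2f}; ")
    buf.write(f"log-likelihood = {result.loglik:.1f}; N obs = {result.n_obs}; N subjects = {result.n_subjects}\n")
    return buf.getvalue()


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_ladder(report: LadderReport) -> str:
    """Per-model fit lines (chi2, df, p, ratio, CFI, IFI, RMSEA with CI) and
    the nested comparisons and decisions along the ladder."""
    if not report.steps:
        raise ValueError("empty ladder report")
    lines = ["Model ladder", "=" * 12]
    for s in report.steps:
        lines.append(f"\n[{s.name}]")
        lines.append("  " + s.fit_line())
        if s.comparison is not None:
            c = s.comparison
            lines.append(f"  vs predecessor: chi2 change = {c.dchisq:.2f}, df = {c.ddf}, p = {_fmt_p(c.p)}")
        if s.decision:
            lines.append(f"  decision: {s.decision}")
    lines.append("\nDecisions: " + ", ".join(f"{k}={v}" for k, v in report.decisions.items()))
    lines.append(f"Final model: {report.final_model_name}")
    return "\n".join(lines) + "\n"


def write_report(artifacts: dict, path=None) -> str:
    """Render every supplied artifact (``mlm`` -> MLMResult, ``ladder`` ->
    LadderReport) into one text report; optionally write it to ``path``."""
    if not artifacts:
        raise ValueError("no fitted results to report")
    parts = []
    if "mlm" in artifacts:
        parts.append(render_mlm_table(artifacts["mlm"]))
    if "ladder" in artifacts:
        parts.append(render_ladder(artifacts["ladder"]))
    if not parts:
        raise ValueError("no renderable artifacts (expected 'mlm' and/or 'ladder')")
    text = "\n".join(parts)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text
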