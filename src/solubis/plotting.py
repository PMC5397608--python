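"""Minimal plotting helpers: stretch plots and MASS plots (matplotlib)."""

from __future__ import annotations


def stretch_plot(points, ax=None):
    """Scatter of APRs: ΔG_contrib (kcal/mol) vs summed aggregation score.

    CDR-overlapping APRs are coloured by CDR number; the shaded band marks the
    -5..+5 kcal/mol window inside which APRs retain aggregation weight.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"FR": "tab:blue", "CDR1": "tab:green", "CDR2": "tab:orange",
              "CDR3": "tab:red", "mixed": "tab:purple"}
    for p in points:
        ax.scatter(p.dg_contrib, p.tango_sum, c=colors.get(p.region, "grey"),
                   marker="o" if not p.critical else "D")
    ax.axvspan(-5, 5, alpha=0.1, color="red")
    ax.set_xlabel("APR ΔG contribution (kcal/mol)")
    ax.set_ylabel("summed aggregation score")
    return ax


def mass_plot(candidates, ax=None, max_ddg: float | None = None):
    """Mutant aggregation and stability spectrum: Δaggregation vs ΔΔG."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter([c.d_tango for c in candidates], [c.ddg for c in candidates], s=12)
    if max_ddg is not None:
        ax.axhline(max_ddg, ls="--", color="red")
    ax.set_xlabel("change in APR aggregation score")
    ax.set_ylabel("predicted ΔΔG (kcal/mol)")
    return ax
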