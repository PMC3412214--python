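"""Plot helpers for monitoring-policy curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_policy_curves"]

_STYLES = {0.10: ":", 0.05: "--", 0.01: "-"}


def plot_policy_curves(policy: pd.DataFrame, ax=None, threshold: float = 55.0):
    """Recommended rescan interval against baseline diameter, one curve per
    risk limit (the conventional 1% solid / 5% dashed / 10% dotted styling)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for limit, grp in policy.groupby("risk_limit"):
        grp = grp.sort_values("baseline")
        ax.plot(
            grp["baseline"],
            grp["interval"],
            _STYLES.get(round(float(limit), 2), "-"),
            label=f"{limit:.0%} probability",
        )
    ax.set_xlabel("baseline diameter (mm)")
    ax.set_ylabel("rescan interval (years)")
    ax.set_title(f"Interval keeping P(observed ≥ {threshold:g} mm) within limit")
    ax.legend()
    return ax
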