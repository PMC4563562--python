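"""Assemble result artifacts from fitted models.

Partition tables (variance fractions per chromosome or per SNP), the
chromosome-length correlation, known-loci summaries, liability-scale
summary lines, and simple trace/posterior figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GRCH37_CHROMOSOME_LENGTHS
from .errors import InvalidInputError


@dataclass
class PartitionTable:
    """Per-unit variance fractions with an explicitly sourced total row.

    ``rows``: DataFrame with columns ``label, fraction, se``;
    ``total``/``total_se``: the total variance fraction;
    ``total_source``: how the total was obtained (``"sum"`` of rows or
    a ``"whole-set fit"``) - the two need not agree.
    """

    rows: pd.DataFrame
    total: float
    total_se: float | None = None
    total_source: str = "sum"

    def __post_init__(self) -> None:
        need = {"label", "fraction", "se"} - set(self.rows.columns)
        if need:
            raise InvalidInputError(f"partition table lacks columns {sorted(need)}")

    @classmethod
    def from_rows(cls, labels, fractions, ses=None) -> "PartitionTable":
        fr = np.asarray(fractions, dtype=float)
        rows = pd.DataFrame(
            {
                "label": list(labels),
                "fraction": fr,
                "se": np.full(fr.size, np.nan) if ses is None else np.asarray(ses),
            }
        )
        return cls(rows, float(fr.sum()), total_source="sum")

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        total = pd.DataFrame(
            {
                "label": [f"total ({self.total_source})"],
                "fraction": [self.total],
                "se": [np.nan if self.total_se is None else self.total_se],
            }
        ).astype(out.dtypes.to_dict(), errors="ignore")
        pd.concat([out, total]).to_csv(path, sep="\t", index=False)

    def to_markdown(self) -> str:
        lines = ["| unit | fraction of variance | SE |", "| --- | --- | --- |"]
        for _, r in self.rows.iterrows():
            se = "" if pd.isna(r["se"]) else f"{r['se']:.4f}"
            lines.append(f"| {r['label']} | {r['fraction']:.4f} | {se} |")
        se = "" if self.total_se is None else f"{self.total_se:.4f}"
        lines.append(f"| total ({self.total_source}) | {self.total:.4f} | {se} |")
        return "\n".join(lines)


def chromosome_length_correlation(
    table: PartitionTable, lengths: dict | None = None
) -> tuple[float, float]:
    """Pearson correlation of variance fractions with chromosome lengths.

    ``lengths`` maps chromosome label -> base-pair length (default
    GRCh37 autosomes). Returns (r, two-sided p) from the t transform
    with n - 2 df.
    """
    if len(table.rows) < 3:
        raise InvalidInputError("need at least 3 chromosomes")
    lengths = lengths or GRCH37_CHROMOSOME_LENGTHS

    def _len(label):
        key = label
        if isinstance(label, str) and label.startswith("chr"):
            key = label[3:]
        try:
            key = int(key)
        except (TypeError, ValueError):
            pass
        if key not in lengths:
            raise InvalidInputError(f"no length known for chromosome {label!r}")
        return lengths[key]

    x = np.array([_len(l) for l in table.rows["label"]], dtype=float)
    y = table.rows["fraction"].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise InvalidInputError("zero variance in fractions or lengths")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def known_loci_summary(per_snp: PartitionTable, total_h2: float) -> tuple[float, float]:
    """Collective variance of known loci and their share of total h2."""
    if len(per_snp.rows) == 0:
        raise InvalidInputError("empty per-SNP table")
    if total_h2 <= 0:
        raise InvalidInputError("total_h2 must be positive")
    s = float(per_snp.rows["fraction"].sum())
    return s, s / total_h2


def liability_summary_lines(h2_obs, h2_obs_se, ctx) -> list[str]:
    """Human-readable observed- and liability-scale summary with 95% CIs."""
    factor = ctx.obs_to_liab_factor
    h2l = h2_obs * factor
    sel = h2_obs_se * factor
    return [
        f"h2 (observed scale) = {h2_obs:.4f} (SE {h2_obs_se:.4f}, "
        f"95% CI {h2_obs - 1.96 * h2_obs_se:.4f}-{h2_obs + 1.96 * h2_obs_se:.4f})",
        f"h2 (liability scale, K={ctx.K}, P={ctx.P:.4f}) = {h2l:.4f} "
        f"(SE {sel:.4f}, 95% CI {h2l - 1.96 * sel:.4f}-{h2l + 1.96 * sel:.4f})",
    ]


def plot_chain(chain, path) -> None:
    """Trace and posterior-density panel for a posterior h2 chain (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(9, 3.2), gridspec_kw={"width_ratios": [2, 1]}
    )
    ax1.plot(chain.h2, lw=0.5)
    ax1.set_xlabel("retained sample")
    ax1.set_ylabel("h2")
    ax1.set_title("trace")
    ax2.hist(chain.h2, bins=40, density=True, orientation="horizontal")
    ax2.set_xlabel("density")
    ax2.set_title("posterior")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
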