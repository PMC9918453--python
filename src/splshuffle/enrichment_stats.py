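"""Population-level statistics over called chimera codes.

Turns per-sequence block codes into the study's headline outputs:
per-block parent-label frequency tables (heatmap data), library diversity
and read-count skew, fold enrichment between populations, and a ranking of
block positions by cross-condition divergence that identifies the
specificity-determining block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import entropy

from .library_model import ChimeraCode


def _as_code(code) -> ChimeraCode:
    return code if isinstance(code, ChimeraCode) else ChimeraCode.parse(str(code))


@dataclass(frozen=True)
class FrequencyTable:
    """Block-position x parent-label frequency matrix for one population."""

    population: str
    table: pd.DataFrame  # columns: block, label, count, frequency
    n_sequences: int

    def frequencies(self, block: int) -> pd.Series:
        sub = self.table[self.table["block"] == block]
        return sub.set_index("label")["frequency"]

    def labels(self, block: int) -> set[str]:
        return set(self.table.loc[self.table["block"] == block, "label"])

    @property
    def n_blocks(self) -> int:
        return int(self.table["block"].max())


def block_frequencies(
    codes: Iterable,
    weights: Sequence[float] | None = None,
    population: str = "population",
) -> FrequencyTable:
    """Empirical per-block label frequencies over resolved codes.

    ``weights`` (e.g. read counts per code) switch from per-sequence to
    weighted counting; merged labels (``D/F``) are first-class categories.
    """
    codes = [_as_code(c) for c in codes]
    if not codes:
        raise ValueError("no resolved codes: cannot compute block frequencies")
    n_blocks = codes[0].n_blocks
    if any(c.n_blocks != n_blocks for c in codes):
        raise ValueError("codes have inconsistent block counts")
    if weights is None:
        weights = [1.0] * len(codes)
    weights = list(weights)
    if len(weights) != len(codes):
        raise ValueError("weights length must match codes")
    rows = []
    for b in range(1, n_blocks + 1):
        counts: dict[str, float] = {}
        for c, w in zip(codes, weights):
            lab = c.labels_per_block[b - 1]
            counts[lab] = counts.get(lab, 0.0) + w
        total = sum(counts.values())
        for lab in sorted(counts):
            rows.append(
                dict(block=b, label=lab, count=counts[lab], frequency=counts[lab] / total)
            )
    return FrequencyTable(population, pd.DataFrame(rows), n_sequences=len(codes))


def diversity_and_skew(
    code_counts: Mapping | pd.Series, theoretical_diversity: int
) -> dict[str, float]:
    """Unique variants, coverage of the theoretical diversity, and read-count skew.

    Skew is the maximum read count over the median read count across
    observed variants.
    """
    if isinstance(code_counts, pd.Series):
        counts = code_counts.to_numpy(dtype=float)
    else:
        counts = np.array(list(code_counts.values()), dtype=float)
    if (counts < 1).any():
        raise ValueError("read counts must be >= 1")
    unique = int(counts.size)
    return {
        "unique_variants": unique,
        "coverage": unique / theoretical_diversity,
        "skew": float(counts.max() / np.median(counts)),
    }


def fold_enrichment(
    output: FrequencyTable, input: FrequencyTable, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-(block, label) frequency ratio output/input with pseudocount damping.

    The ratio is ``(f_out + e_out) / (f_in + e_in)`` with
    ``e = pseudocount / n_sequences`` of the respective population, so a
    label absent from the input yields a large finite ratio rather than a
    division by zero.
    """
    if output.n_blocks != input.n_blocks:
        raise ValueError("populations have different block counts")
    eps_out = pseudocount / output.n_sequences
    eps_in = pseudocount / input.n_sequences
    rows = []
    for b in range(1, input.n_blocks + 1):
        f_out = output.frequencies(b)
        f_in = input.frequencies(b)
        for lab in sorted(output.labels(b) | input.labels(b)):
            fo = float(f_out.get(lab, 0.0))
            fi = float(f_in.get(lab, 0.0))
            rows.append(
                dict(
                    block=b,
                    label=lab,
                    freq_out=fo,
                    freq_in=fi,
                    fold_enrichment=(fo + eps_out) / (fi + eps_in),
                )
            )
    return pd.DataFrame(rows)


def _aligned_distributions(
    tables: Sequence[FrequencyTable], block: int
) -> np.ndarray:
    labels = sorted(set().union(*(t.labels(block) for t in tables)))
    mat = np.zeros((len(tables), len(labels)))
    for r, t in enumerate(tables):
        f = t.frequencies(block)
        for c, lab in enumerate(labels):
            mat[r, c] = float(f.get(lab, 0.0))
    return mat


def identify_specificity_block(
    tables: Mapping[str, FrequencyTable] | Sequence[FrequencyTable],
) -> pd.DataFrame:
    """Rank block positions by mean pairwise Jensen-Shannon divergence across
    conditions (descending; ties broken by block index).

    The block whose label distribution differs most between selection
    conditions is the candidate specificity-determining block.
    Divergences are JSD in bits (base 2), in [0, 1].
    """
    ts = list(tables.values()) if isinstance(tables, Mapping) else list(tables)
    if len(ts) < 2:
        raise ValueError("need at least two conditions")
    n_blocks = ts[0].n_blocks
    if any(t.n_blocks != n_blocks for t in ts):
        raise ValueError("conditions have inconsistent block counts")
    rows = []
    for b in range(1, n_blocks + 1):
        mat = _aligned_distributions(ts, b)
        divs = []
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                divs.append(jensenshannon(mat[i], mat[j], base=2) ** 2)
        rows.append(dict(block=b, mean_jsd=float(np.mean(divs))))
    df = pd.DataFrame(rows).sort_values(
        ["mean_jsd", "block"], ascending=[False, True], ignore_index=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def block_entropy(table: FrequencyTable, block: int) -> float:
    """Shannon entropy (nats) of the label distribution at one block."""
    return float(entropy(_aligned_distributions([table], block)[0]))


def frequency_long_table(tables: Mapping[str, FrequencyTable]) -> pd.DataFrame:
    """Tidy (population, block, label, count, frequency) table for export."""
    out = []
    for name, t in tables.items():
        df = t.table.copy()
        df.insert(0, "population", name)
        out.append(df)
    return pd.concat(out, ignore_index=True)


def plot_block_frequency_heatmap(
    tables: Mapping[str, FrequencyTable], path, labels: Sequence[str] | None = None
) -> None:
    """One frequency heatmap (block x label) per population, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(tables)
    if labels is None:
        labels = sorted(
            set().union(
                *(t.labels(b) for t in tables.values() for b in range(1, t.n_blocks + 1))
            )
        )
    fig, axes = plt.subplots(
        1, len(names), figsize=(3.2 * len(names), 3.2), squeeze=False
    )
    for ax, name in zip(axes[0], names):
        t = tables[name]
        mat = np.zeros((t.n_blocks, len(labels)))
        for b in range(1, t.n_blocks + 1):
            f = t.frequencies(b)
            for c, lab in enumerate(labels):
                mat[b - 1, c] = float(f.get(lab, 0.0))
        im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis", aspect="auto")
        ax.set_xticks(range(len(labels)), labels, fontsize=7)
        ax.set_yticks(range(t.n_blocks), [str(b) for b in range(1, t.n_blocks + 1)])
        ax.set_xlabel("parent label")
        ax.set_ylabel("block")
        ax.set_title(name, fontsize=9)
    fig.colorbar(im, ax=axes[0], shrink=0.8, label="frequency")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
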