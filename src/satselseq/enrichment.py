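"""Generational frequency trajectories, logos and replicate concordance.

Counts per (library, generation, codon) become codon- and amino-acid-level
frequency vectors; final-generation frequencies are summarized as a logo
matrix, optionally corrected for the starting-library composition (the NNS
expansion over-represents residues with several codons, e.g. Arg with
three, so raw final frequencies conflate selection with codon
multiplicity); replicate libraries are compared with Euclidean distance
and cosine similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import AA_SYMBOLS, CODONS, translate
from .demux import CountTable

_CODON_TO_AA = {c: translate(c) for c in CODONS}


@dataclass
class FrequencyMatrix:
    """Per-(library, generation) codon and amino-acid frequency vectors.

    ``codon`` and ``aa`` are DataFrames indexed by (library, generation)
    with codon / symbol columns; every row sums to 1. ``depth`` holds the
    read depth behind each row so counts can be recovered.
    """

    codon: pd.DataFrame
    aa: pd.DataFrame
    depth: pd.Series

    def libraries(self) -> list[str]:
        return sorted({lib for lib, _ in self.codon.index})

    def generations(self, library: str | None = None) -> list[str]:
        gens = {gen for lib, gen in self.codon.index if library is None or lib == library}
        return sorted(gens)

    def aa_vector(self, library: str, generation: str) -> pd.Series:
        return self.aa.loc[(library, generation)]

    def aa_counts(self, library: str, generation: str) -> pd.Series:
        return self.aa.loc[(library, generation)] * self.depth.loc[(library, generation)]

    def to_long_frame(self, level: str = "aa") -> pd.DataFrame:
        df = self.aa if level == "aa" else self.codon
        long = df.stack().rename("frequency").reset_index()
        long.columns = ["library", "generation", "symbol" if level == "aa" else "codon", "frequency"]
        return long


def frequencies(table: CountTable) -> FrequencyMatrix:
    """Normalize a count table into frequency vectors.

    Codon frequency = count/depth per (library, generation); amino-acid
    frequency aggregates synonymous codons. Cells with zero depth are
    omitted with a warning.
    """
    cells: dict[tuple[str, str], np.ndarray] = {}
    for (lib, gen, codon), n in table.counts.items():
        vec = cells.setdefault((lib, gen), np.zeros(len(CODONS)))
        vec[CODONS.index(codon)] += n
    index, codon_rows, aa_rows, depths = [], [], [], []
    for key in sorted(cells):
        vec = cells[key]
        depth = vec.sum()
        if depth == 0:
            warnings.warn(f"zero read depth for {key}; cell omitted", stacklevel=2)
            continue
        index.append(key)
        depths.append(depth)
        codon_rows.append(vec / depth)
        aa_vec = np.zeros(len(AA_SYMBOLS))
        for i, codon in enumerate(CODONS):
            aa_vec[AA_SYMBOLS.index(_CODON_TO_AA[codon])] += vec[i]
        aa_rows.append(aa_vec / depth)
    idx = pd.MultiIndex.from_tuples(index, names=["library", "generation"])
    return FrequencyMatrix(
        codon=pd.DataFrame(codon_rows, index=idx, columns=list(CODONS)),
        aa=pd.DataFrame(aa_rows, index=idx, columns=list(AA_SYMBOLS)),
        depth=pd.Series(depths, index=idx, name="depth"),
    )


def logo_matrix(
    freqs: FrequencyMatrix,
    generation: str = "G3",
    mode: str = "raw",
    baseline_generation: str = "G0",
    pseudocount: float = 0.5,
    position_of: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-position amino-acid logo heights (rows sum to 1).

    ``raw`` heights are the chosen generation's amino-acid frequencies.
    ``corrected`` heights are enrichment ratios against the starting
    library: e(aa) = (c_T(aa)+α)/Σ ÷ (c_0(aa)+α)/Σ with pseudocount α per
    symbol, renormalized per position. Symbols absent from both
    generations get height 0, so correction is over represented symbols.
    Rows are indexed by residue when ``position_of`` maps library ids to
    residue numbers, else by library id.
    """
    if mode not in ("raw", "corrected"):
        raise ValueError(f"mode must be 'raw' or 'corrected', got {mode!r}")
    rows = {}
    for lib in freqs.libraries():
        if (lib, generation) not in freqs.aa.index:
            continue
        f_t = freqs.aa_vector(lib, generation)
        if mode == "raw":
            heights = f_t.to_numpy()
        else:
            if (lib, baseline_generation) not in freqs.aa.index:
                raise ValueError(f"corrected mode requires a {baseline_generation} vector for {lib}")
            c_t = freqs.aa_counts(lib, generation).to_numpy()
            c_0 = freqs.aa_counts(lib, baseline_generation).to_numpy()
            present = (c_t > 0) | (c_0 > 0)
            num = (c_t + pseudocount) / (c_t + pseudocount).sum()
            den = (c_0 + pseudocount) / (c_0 + pseudocount).sum()
            heights = np.where(present, num / den, 0.0)
        total = heights.sum()
        if total <= 0:
            raise ValueError(f"no mass at {lib}/{generation}")
        rows[lib] = heights / total
    logo = pd.DataFrame(rows, index=list(AA_SYMBOLS)).T
    if position_of:
        logo.index = [position_of.get(lib, lib) for lib in logo.index]
        logo = logo.sort_index()
    logo.attrs["mode"] = mode
    return logo


@dataclass(frozen=True)
class ConcordanceReport:
    """Replicate agreement between two frequency vectors."""

    euclidean_distance: float
    cosine_similarity: float
    generation: str | None = None

    def to_dict(self) -> dict:
        return {
            "euclidean_distance": self.euclidean_distance,
            "cosine_similarity": self.cosine_similarity,
            "generation": self.generation,
        }


def concordance(f1: pd.Series, f2: pd.Series, generation: str | None = None) -> ConcordanceReport:
    """Euclidean distance and cosine similarity over a shared symbol space."""
    if not f1.index.equals(f2.index):
        f2 = f2.reindex(f1.index)
        if f2.isna().any():
            raise ValueError("frequency vectors must share the same symbol space")
    a, b = f1.to_numpy(float), f2.to_numpy(float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return ConcordanceReport(
        euclidean_distance=float(np.linalg.norm(a - b)),
        cosine_similarity=float(a @ b / (na * nb)),
        generation=generation,
    )


@dataclass
class TrajectoryReport:
    """Per-symbol generational frequency series with fixation flags."""

    series: pd.DataFrame      # symbols x generations
    fixation: pd.DataFrame    # bool, same shape
    threshold: float

    def fixed_symbols(self, generation: str | None = None) -> list[str]:
        gen = generation or self.series.columns[-1]
        return list(self.fixation.index[self.fixation[gen]])


def trajectory_report(
    freqs: FrequencyMatrix,
    library: str,
    level: str = "aa",
    threshold: float = 0.9,
) -> TrajectoryReport:
    """Track each symbol's frequency across generations for one library.

    A symbol is flagged as fixed in a generation when its frequency
    exceeds ``threshold`` (default 0.9, the near-fixation criterion used
    to call positions like Leu113 that end >90% wild type).
    """
    gens = freqs.generations(library)
    if len(gens) < 2:
        raise ValueError("trajectory report needs at least two generations")
    df = freqs.aa if level == "aa" else freqs.codon
    series = pd.DataFrame({gen: df.loc[(library, gen)] for gen in gens})
    return TrajectoryReport(series=series, fixation=series > threshold, threshold=threshold)


def plot_logo(logo: pd.DataFrame, path=None, ax=None):
    """Render a logo matrix as stacked per-position letters (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.7 * len(logo)), 3))
    cmap = plt.get_cmap("tab20")
    colors = {sym: cmap(i % 20) for i, sym in enumerate(AA_SYMBOLS)}
    for x, (_, row) in enumerate(logo.iterrows()):
        bottom = 0.0
        for sym in row.sort_values().index:
            h = row[sym]
            if h < 0.01:
                continue
            ax.text(
                x, bottom + h / 2, sym, ha="center", va="center",
                fontsize=6 + 16 * h, color=colors[sym], fontweight="bold",
            )
            bottom += h
    ax.set_xticks(range(len(logo)))
    ax.set_xticklabels([str(i) for i in logo.index])
    ax.set_ylim(0, 1)
    ax.set_ylabel("frequency" if logo.attrs.get("mode") == "raw" else "relative enrichment")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
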