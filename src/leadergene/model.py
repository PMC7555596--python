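"""Model/Results interface for the full leader-gene analysis.

`LeaderGeneModel` holds the data (gene panel + interaction network) and the
analysis parameters; `fit(seed)` runs threshold → WNL → orphan split → gap
k-selection → exact k-means → Kruskal–Wallis → centroid-ordered labeling and
returns a `LeaderGeneResults` carrying the estimates, diagnostics, a
`summary()` table and writers for the standard output artifacts
(assignments TSV, run-report JSON, gap-curve TSV).

Two orphan-handling modes exist because "exclude orphans from the study"
and "count the orphan class among the clusters" are both defensible
readings of the procedure:

* ``preseparate`` (default): orphans (WNL = 0) are split off
  deterministically, clustering runs on the linked genes only, and the
  report counts k + 1 classes when orphans exist.
* ``include``: the full WNL vector (zeros included) is clustered; a cluster
  whose centroid is exactly 0 is relabeled "orphan".
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    Clustering,
    ClusterLabeling,
    GapCurve,
    KWResult,
    gap_select_k,
    kmeans_1d_exact,
    kruskal_wallis,
    label_clusters,
)
from .io import (
    AliasMap,
    file_sha256,
    load_gene_list,
    load_interaction_scores,
    normalize_symbol,
    write_assignments,
)
from .wnl import OrphanPartition, compute_wnl, partition_orphans

__all__ = ["LeaderGeneModel", "LeaderGeneResults", "PipelineError"]

ORPHAN_MODES = ("preseparate", "include")


class PipelineError(RuntimeError):
    """Raised when the analysis cannot proceed on the given inputs."""


class LeaderGeneModel:
    """Leader-gene analysis of a gene panel on a scored interaction network.

    Parameters
    ----------
    panel : iterable of gene symbols (normalised, de-duplicated).
    network : undirected ``networkx.Graph`` with a ``score`` in [0, 1] on
        every edge (as produced by :func:`leadergene.load_interaction_scores`).
    tau : confidence threshold; only edges with score >= tau count (0.9,
        the database's "highest confidence" band, by default).
    kmin, kmax : k range scanned by the gap statistic (default 2..12).
    alpha : Kruskal–Wallis significance level (default 0.01).
    B : number of gap-statistic reference datasets (default 100).
    orphan_mode : "preseparate" or "include" (see module docstring).
    """

    def __init__(
        self,
        panel: Iterable[str],
        network: nx.Graph,
        *,
        tau: float = 0.9,
        kmin: int = 2,
        kmax: int = 12,
        alpha: float = 0.01,
        B: int = 100,
        orphan_mode: str = "preseparate",
        input_checksums: Mapping[str, str] | None = None,
    ):
        self.panel = frozenset(normalize_symbol(g) for g in panel)
        if not self.panel:
            raise ValueError("empty gene panel")
        self.network = network
        self.tau = float(tau)
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau must lie in (0, 1], got {tau}")
        self.kmin, self.kmax = int(kmin), int(kmax)
        if self.kmin < 1 or self.kmin > self.kmax:
            raise ValueError(f"invalid k range [{kmin}, {kmax}]")
        self.alpha = float(alpha)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        self.B = int(B)
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if orphan_mode not in ORPHAN_MODES:
            raise ValueError(
                f"orphan_mode must be one of {ORPHAN_MODES}, got {orphan_mode!r}"
            )
        self.orphan_mode = orphan_mode
        self.input_checksums = dict(input_checksums or {})
        self.unresolved_symbols: tuple[str, ...] = ()

    @classmethod
    def from_files(
        cls,
        panel_path: str | Path,
        scores_path: str | Path,
        alias_path: str | Path | None = None,
        scale: str = "auto",
        **kwargs,
    ) -> "LeaderGeneModel":
        """Build a model from a panel file and a STRING-dialect links file."""
        alias = AliasMap.from_tsv(alias_path) if alias_path else None
        panel_res = load_gene_list(panel_path, alias)
        net = load_interaction_scores(scores_path, scale=scale)
        checksums = {
            "panel_sha256": file_sha256(panel_path),
            "scores_sha256": file_sha256(scores_path),
        }
        if alias_path:
            checksums["aliases_sha256"] = file_sha256(alias_path)
        model = cls(panel_res.genes, net, input_checksums=checksums, **kwargs)
        model.unresolved_symbols = panel_res.unresolved
        return model

    def config(self) -> dict:
        return {
            "tau": self.tau,
            "kmin": self.kmin,
            "kmax": self.kmax,
            "alpha": self.alpha,
            "B": self.B,
            "orphan_mode": self.orphan_mode,
        }

    def fit(self, seed: int = 0) -> "LeaderGeneResults":
        """Run the full analysis; deterministic given the seed.

        The single seed governs the only stochastic stage (gap-statistic
        reference draws) and is echoed in the results.
        """
        warnings: list[str] = []
        wnl = compute_wnl(self.network, self.panel, self.tau)
        part = partition_orphans(wnl)
        if not part.linked:
            raise PipelineError(
                "all panel genes are orphans: no interaction at or above "
                f"tau={self.tau}"
            )

        if self.orphan_mode == "preseparate":
            cluster_genes = sorted(part.linked)
            labeling_orphans: frozenset[str] = part.orphans
        else:
            cluster_genes = list(wnl.index)
            labeling_orphans = frozenset()
        values = wnl[cluster_genes].to_numpy()

        n_distinct = len(np.unique(values))
        if n_distinct < max(2, self.kmin):
            raise PipelineError(
                "insufficient linked genes for clustering: "
                f"{n_distinct} distinct WNL value(s), kmin={self.kmin}"
            )
        gap = gap_select_k(
            values, kmin=self.kmin, kmax=self.kmax, B=self.B, seed=seed
        )
        warnings.extend(gap.warnings)

        clustering = kmeans_1d_exact(values, gap.k_selected)
        labeling = label_clusters(clustering, cluster_genes, labeling_orphans)
        if self.orphan_mode == "include":
            labeling = _relabel_zero_cluster(labeling)

        groups = [
            values[clustering.labels == c] for c in range(clustering.k)
        ]
        kw = kruskal_wallis(groups, alpha=self.alpha)
        if not kw.significant:
            warnings.append(
                f"Kruskal-Wallis not significant (p={kw.p:.4g} >= "
                f"alpha={self.alpha}); cluster separation unverified"
            )

        return LeaderGeneResults(
            model=self,
            seed=int(seed),
            wnl=wnl,
            partition=part,
            gap=gap,
            clustering=clustering,
            labeling=labeling,
            kw=kw,
            warnings=tuple(warnings),
        )


def _relabel_zero_cluster(labeling: ClusterLabeling) -> ClusterLabeling:
    """In include mode, the cluster with centroid exactly 0 is the orphan class."""
    zero_labels = [
        lab for lab, c in labeling.centroid_by_label.items() if c == 0.0
    ]
    if not zero_labels:
        return labeling
    zero = zero_labels[0]
    labels = {
        g: ("orphan" if lab == zero else lab) for g, lab in labeling.labels.items()
    }
    centroids = {
        ("orphan" if lab == zero else lab): c
        for lab, c in labeling.centroid_by_label.items()
    }
    return ClusterLabeling(labels=labels, centroid_by_label=centroids)


@dataclass(frozen=True)
class LeaderGeneResults:
    """Fitted leader-gene analysis: estimates, diagnostics, writers."""

    model: LeaderGeneModel
    seed: int
    wnl: pd.Series
    partition: OrphanPartition
    gap: GapCurve
    clustering: Clustering
    labeling: ClusterLabeling
    kw: KWResult
    warnings: tuple[str, ...] = ()

    # -- derived quantities -------------------------------------------------

    @property
    def labels(self) -> pd.Series:
        """Cluster label per panel gene (letters + "orphan"), sorted by symbol."""
        return pd.Series(self.labeling.labels, name="cluster").sort_index()

    @property
    def leaders(self) -> list[str]:
        """Members of cluster "A" — the leader genes."""
        return self.labeling.leaders

    @property
    def cluster_sizes(self) -> dict[str, int]:
        """Size per output class, letters in centroid order then "orphan"."""
        sizes = self.labeling.sizes()
        order = sorted(
            sizes,
            key=lambda lab: (lab == "orphan", -self.labeling.centroid_by_label[lab]),
        )
        return {lab: sizes[lab] for lab in order}

    @property
    def n_classes(self) -> int:
        """Total number of output classes, orphan class included when present."""
        return len(self.cluster_sizes)

    # -- reporting ----------------------------------------------------------

    def to_report(self, timestamp: bool = True) -> dict:
        """JSON-able run report with counts, curves, test results and provenance."""
        sizes = self.cluster_sizes
        n_orph, n_link = len(self.partition.orphans), len(self.partition.linked)
        assert n_orph + n_link == len(self.wnl)
        assert sum(sizes.values()) == len(self.wnl)
        report = {
            "tool": {"name": "leadergene", "version": __version__},
            "config": {**self.model.config(), "seed": self.seed},
            "inputs": dict(self.model.input_checksums),
            "unresolved_symbols": list(self.model.unresolved_symbols),
            "counts": {
                "panel": len(self.wnl),
                "orphans": n_orph,
                "linked": n_link,
                "classes": self.n_classes,
                "per_cluster": sizes,
            },
            "centroids": {
                lab: self.labeling.centroid_by_label[lab] for lab in sizes
            },
            "leaders": self.leaders,
            "gap": self.gap.to_dict(),
            "kruskal_wallis": self.kw.to_dict(),
            "warnings": list(self.warnings),
        }
        if timestamp:
            report["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return report

    def summary(self) -> str:
        """Human-readable summary table of the fitted analysis."""
        sizes = self.cluster_sizes
        w = 66
        lines = [
            "Leader Gene Analysis".center(w),
            "=" * w,
            f"{'Genes in panel:':<24}{len(self.wnl):>8}"
            f"    {'tau:':<16}{self.model.tau:>10.3g}",
            f"{'Linked (WNL > 0):':<24}{len(self.partition.linked):>8}"
            f"    {'k range:':<16}{f'{self.model.kmin}-{self.model.kmax}':>10}",
            f"{'Orphans (WNL = 0):':<24}{len(self.partition.orphans):>8}"
            f"    {'alpha:':<16}{self.model.alpha:>10.3g}",
            f"{'Clusters selected (k):':<24}{self.gap.k_selected:>8}"
            f"    {'B (reference):':<16}{self.model.B:>10}",
            f"{'Output classes:':<24}{self.n_classes:>8}"
            f"    {'seed:':<16}{self.seed:>10}",
            "-" * w,
            f"{'Cluster':<10}{'Size':>6}{'WNL centroid':>16}",
        ]
        for lab, size in sizes.items():
            lines.append(
                f"{lab:<10}{size:>6}{self.labeling.centroid_by_label[lab]:>16.4f}"
            )
        lines += [
            "-" * w,
            f"Kruskal-Wallis: H = {self.kw.H:.4f}, df = {self.kw.df}, "
            f"p = {self.kw.p:.4g} "
            f"({'significant' if self.kw.significant else 'NOT significant'} "
            f"at alpha = {self.kw.alpha:g})",
            "Leaders (cluster A): " + ", ".join(self.leaders),
        ]
        for msg in self.warnings:
            lines.append(f"Warning: {msg}")
        lines.append("=" * w)
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write assignments TSV, report JSON and gap-curve TSV to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "assignments": outdir / "assignments.tsv",
            "report": outdir / "report.json",
            "gap_curve": outdir / "gap_curve.tsv",
        }
        write_assignments(self.labeling.labels, self.wnl, paths["assignments"])
        paths["report"].write_text(
            json.dumps(self.to_report(), indent=2, sort_keys=True) + "\n"
        )
        self.gap.to_frame().to_csv(paths["gap_curve"], sep="\t", index=False)
        return paths

    # -- plotting -----------------------------------------------------------

    def plot_gap(self, ax=None):
        """Gap curve with 1-SE error bars and the selected k highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(
            self.gap.k_range, self.gap.gap, yerr=self.gap.se,
            fmt="o-", capsize=3, label="gap(k)",
        )
        ax.axvline(self.gap.k_selected, ls="--", color="grey",
                   label=f"k = {self.gap.k_selected}")
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("gap statistic")
        ax.legend()
        return ax

    def plot_wnl(self, ax=None):
        """WNL values in descending order, coloured by cluster label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = self.wnl.sort_values(ascending=False)
        labs = self.labels[order.index]
        for lab in self.cluster_sizes:
            mask = (labs == lab).to_numpy()
            ax.plot(
                np.nonzero(mask)[0], order[mask], "o", ms=4, label=lab
            )
        ax.set_xlabel("gene rank")
        ax.set_ylabel("WNL")
        ax.legend(title="cluster")
        return ax
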