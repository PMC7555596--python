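"""Synthetic STRING-like networks with planted tier structure.

The generator emulates the statistical shape of a curated disease panel
scored against a high-confidence interaction database: a small, densely and
strongly connected leader tier; one or more mid-connectivity tiers; and a
block of genes whose every interaction (if any) falls below the confidence
threshold tau, so their WNL is exactly zero (orphans).  Ground-truth tier
membership is returned alongside the network, which makes every pipeline
stage testable without any external download.

Edge scores are drawn from truncated Beta-like families parameterised by a
mode and a concentration, clipped to the stated support — [tau, 1] for
supra-threshold ("high") scores, [0, tau) for sub-threshold ("low") ones —
so the orphan guarantee is enforced by construction, not by rejection.
A ``concentration`` of ``None`` degenerates to a point mass at the mode,
handy for hand-computable examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .io import write_gene_list, write_links

__all__ = [
    "PAPER_LEADER_SYMBOLS",
    "ScoreDist",
    "SyntheticTruth",
    "TierSpec",
    "generate_flat_null",
    "generate_network",
    "study_like_tiers",
    "tiers_from_dict",
]

#: The twelve leader-gene symbols from the periodontitis–colorectal cancer
#: panel, reusable for documentation examples via ``use_leader_names=True``.
PAPER_LEADER_SYMBOLS = (
    "CBL", "CTNNB1", "FOS", "GRB2", "IL1B", "IL4",
    "IL6", "IL10", "JUN", "PIK3CA", "PIK3R1", "RELA",
)


@dataclass(frozen=True)
class ScoreDist:
    """Score distribution: scaled Beta with given mode, or a point mass.

    ``concentration`` controls spread (larger = tighter around the mode);
    ``None`` means exactly the mode every draw.
    """

    mode: float
    concentration: float | None = None

    def sample(self, rng: np.random.Generator, low: float, high: float) -> float:
        if not low <= self.mode <= high:
            raise ValueError(
                f"score mode {self.mode} outside support [{low}, {high}]"
            )
        if self.concentration is None:
            return float(self.mode)
        m = (self.mode - low) / (high - low)
        a = 1.0 + self.concentration * m
        b = 1.0 + self.concentration * (1.0 - m)
        return float(low + (high - low) * rng.beta(a, b))


@dataclass(frozen=True)
class TierSpec:
    """One planted tier of the synthetic network.

    A tier with ``score_high is None`` is an orphan tier: every edge touching
    it (within the tier or across) is drawn from a sub-tau distribution, so
    its genes can never acquire a retained link.  ``cross_p`` maps *other*
    tier names to the probability of an edge between a gene here and a gene
    there.
    """

    name: str
    size: int
    intra_p: float = 0.0
    cross_p: Mapping[str, float] = field(default_factory=dict)
    score_high: ScoreDist | None = None
    score_low: ScoreDist | None = None

    @property
    def is_orphan(self) -> bool:
        return self.score_high is None


@dataclass(frozen=True)
class SyntheticTruth:
    """Generated network plus its planted ground truth."""

    tier_of: dict[str, str]
    network: nx.Graph
    tau: float
    seed: int
    panel: tuple[str, ...]

    def tier_members(self, name: str) -> frozenset[str]:
        return frozenset(g for g, t in self.tier_of.items() if t == name)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit links file (STRING dialect), panel file and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "links": outdir / "links.tsv",
            "panel": outdir / "panel.txt",
            "truth": outdir / "truth.tsv",
        }
        write_links(self.network, paths["links"], scale="unit")
        write_gene_list(self.panel, paths["panel"])
        lines = ["gene\ttier"]
        lines += [f"{g}\t{self.tier_of[g]}" for g in sorted(self.panel)]
        paths["truth"].write_text("\n".join(lines) + "\n")
        return paths


def _validate_tiers(tiers: Sequence[TierSpec], tau: float) -> None:
    if not tiers:
        raise ValueError("at least one tier required")
    names = [t.name for t in tiers]
    if len(set(names)) != len(names):
        raise ValueError(f"tier names must be unique, got {names}")
    for t in tiers:
        if t.size < 1:
            raise ValueError(f"tier {t.name}: size must be >= 1")
        probs = [t.intra_p, *t.cross_p.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"tier {t.name}: probabilities must lie in [0, 1]")
        if t.score_high is not None and not tau <= t.score_high.mode <= 1.0:
            raise ValueError(
                f"tier {t.name}: score_high support below tau "
                f"(mode {t.score_high.mode} not in [{tau}, 1])"
            )
        if t.score_low is not None and not 0.0 <= t.score_low.mode < tau:
            raise ValueError(
                f"tier {t.name}: score_low mode {t.score_low.mode} "
                f"not in [0, {tau})"
            )
        unknown = set(t.cross_p) - set(names)
        if unknown:
            raise ValueError(f"tier {t.name}: cross_p references {sorted(unknown)}")


def _gene_names(tiers: Sequence[TierSpec], use_leader_names: bool) -> list[list[str]]:
    names: list[list[str]] = []
    counter = 0
    for i, t in enumerate(tiers):
        tier_names: list[str] = []
        for j in range(t.size):
            if use_leader_names and i == 0 and j < len(PAPER_LEADER_SYMBOLS):
                tier_names.append(PAPER_LEADER_SYMBOLS[j])
            else:
                counter += 1
                tier_names.append(f"SYN{counter:04d}")
        names.append(tier_names)
    return names


def generate_network(
    tiers: Sequence[TierSpec],
    tau: float = 0.9,
    seed: int = 0,
    use_leader_names: bool = False,
) -> SyntheticTruth:
    """Sample a combined-score network with the given planted tiers.

    Edges are Bernoulli per gene pair — ``intra_p`` within a tier, the
    declaring tier's ``cross_p`` across tiers — with scores from the
    relevant tier's distribution: supra-tau (``score_high``) unless either
    endpoint belongs to an orphan tier, in which case the orphan tier's
    ``score_low`` (default mode tau/2) keeps the edge below threshold.
    Deterministic under ``seed``: same spec + seed reproduces the network
    bit-for-bit.
    """
    tau = float(tau)
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    _validate_tiers(tiers, tau)
    rng = np.random.default_rng(seed)
    names = _gene_names(tiers, use_leader_names)

    net = nx.Graph()
    tier_of: dict[str, str] = {}
    for t, tier_names in zip(tiers, names):
        for g in tier_names:
            net.add_node(g)
            tier_of[g] = t.name

    sub_tau_hi = np.nextafter(tau, 0.0)  # strict upper bound for low scores

    def low_dist(t: TierSpec) -> ScoreDist:
        return t.score_low if t.score_low is not None else ScoreDist(tau / 2.0, 6.0)

    for i, ti in enumerate(tiers):
        for j in range(i, len(tiers)):
            tj = tiers[j]
            if i == j:
                p = ti.intra_p
            else:
                p = ti.cross_p.get(tj.name, tj.cross_p.get(ti.name, 0.0))
            if p == 0.0:
                continue
            if ti.is_orphan or tj.is_orphan:
                owner = ti if ti.is_orphan else tj
                dist, lo, hi = low_dist(owner), 0.0, sub_tau_hi
            else:
                owner = ti if (i == j or tj.name in ti.cross_p) else tj
                dist, lo, hi = owner.score_high, tau, 1.0
            gi, gj = names[i], names[j]
            for a_idx, a in enumerate(gi):
                partners = gj[a_idx + 1 :] if i == j else gj
                for b in partners:
                    if rng.random() < p:
                        net.add_edge(a, b, score=dist.sample(rng, lo, hi))

    panel = tuple(g for tier_names in names for g in tier_names)
    return SyntheticTruth(
        tier_of=tier_of, network=net, tau=tau, seed=int(seed), panel=panel
    )


def generate_flat_null(
    n: int, tau: float = 0.9, seed: int = 0, p: float = 0.3
) -> SyntheticTruth:
    """Homogeneous null network: one tier, no planted structure.

    Every gene pair gets an edge with probability ``p``; scores are uniform
    on a window straddling tau, so some links survive the threshold and some
    do not, without any grouping.  Used to calibrate the gap statistic's
    "no structure" behaviour and the Kruskal–Wallis type-I error.  With
    ``tau = 1.0`` the window sits entirely below 1, so all genes are orphans.
    """
    n = int(n)
    if n < 3:
        raise ValueError("n must be at least 3")
    tau = float(tau)
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    rng = np.random.default_rng(seed)
    genes = [f"SYN{i + 1:04d}" for i in range(n)]
    lo = max(0.0, tau - 0.2)
    hi = min(1.0, tau + 0.1)
    net = nx.Graph()
    net.add_nodes_from(genes)
    for a_idx, a in enumerate(genes):
        for b in genes[a_idx + 1 :]:
            if rng.random() < p:
                net.add_edge(a, b, score=float(rng.uniform(lo, hi)))
    return SyntheticTruth(
        tier_of={g: "null" for g in genes},
        network=net,
        tau=tau,
        seed=int(seed),
        panel=tuple(genes),
    )


def study_like_tiers() -> list[TierSpec]:
    """Default tier spec emulating the reference study's panel shape.

    137 genes: 12 leaders (a near-clique of very strong interactions), a
    mid-connectivity tier of 30 wired mostly to the leaders, a peripheral
    tier of 41 with sparse weaker links, and 54 orphans whose only edges
    (if any) fall below tau.
    """
    return [
        TierSpec(
            "leader", 12, intra_p=1.0, score_high=ScoreDist(0.95, 80.0)
        ),
        TierSpec(
            "mid", 30, intra_p=0.2, cross_p={"leader": 0.6},
            score_high=ScoreDist(0.93, 60.0),
        ),
        TierSpec(
            "peripheral", 41, intra_p=0.12, cross_p={"mid": 0.05},
            score_high=ScoreDist(0.91, 60.0),
        ),
        TierSpec(
            "orphan", 54, intra_p=0.1, score_low=ScoreDist(0.45, 6.0)
        ),
    ]


def tiers_from_dict(spec: Mapping) -> list[TierSpec]:
    """Build tier specs from a plain mapping (e.g. parsed YAML).

    Expected shape::

        tiers:
          - name: leader
            size: 12
            intra_p: 1.0
            cross_p: {mid: 0.6}        # optional
            score_high: {mode: 0.95, concentration: 80}
          - name: orphan
            size: 54
            intra_p: 0.1
            score_low: {mode: 0.45, concentration: 6}
    """
    def dist(d):
        if d is None:
            return None
        return ScoreDist(float(d["mode"]), d.get("concentration"))

    tiers = []
    for t in spec["tiers"]:
        tiers.append(
            TierSpec(
                name=str(t["name"]),
                size=int(t["size"]),
                intra_p=float(t.get("intra_p", 0.0)),
                cross_p={str(k): float(v) for k, v in (t.get("cross_p") or {}).items()},
                score_high=dist(t.get("score_high")),
                score_low=dist(t.get("score_low")),
            )
        )
    return tiers
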