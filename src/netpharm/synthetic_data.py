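"""Synthetic pharmacology datasets with the statistical structure the
downstream analysis assumes.

The generators emulate a screened essential-oil dataset: a compound table
with a controlled drug-like fraction, a heavy-tailed compound->target
interaction table with a few hub ingredients, pathway membership sets with
one dominant pathway and promiscuous hub proteins, and simple graphs
realizing an arbitrary (graphical) degree sequence so printed
degree-distribution tables can be rebuilt as concrete graphs.

All randomness flows through one :class:`numpy.random.Generator` seeded per
dataset; identical config + seed reproduces identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import (
    ComputationError,
    ConfigurationError,
    FixtureLookupError,
    NonGraphicalSequenceError,
    ValidationError,
)
from .io_formats import (
    COMPOUND_COLUMNS,
    PathwayCollection,
    read_gmt,
    read_pajek,
)

# Lipinski rule-of-five bounds used by the generators (the screening module
# owns the authoritative filter; these mirror it so planted pass/fail labels
# agree with the filter's verdicts).
_MW_MAX = 500.0     # strict: pass iff mw < 500
_HBD_MAX = 5        # inclusive
_HBA_MAX = 10       # inclusive
_MLOGP_MAX = 5.0    # inclusive


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults describe a screened essential-oil study: ~91 identified
    compounds of which ~87% are drug-like, 191 candidate protein targets,
    70 annotated pathways, two hub ingredients reaching ~90-110 targets
    each, and one dominant pathway covering ~26% of the targets.
    """

    n_compounds: int = 91
    n_targets: int = 191
    n_pathways: int = 70
    hub_fraction: float = 0.05
    hub_target_range: tuple[int, int] = (90, 110)
    nonhub_target_range: tuple[int, int] = (0, 12)
    dominant_pathway_coverage: float = 0.26
    druglike_fraction: float = 0.87
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_targets", "n_pathways"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        for name in ("hub_fraction", "dominant_pathway_coverage", "druglike_fraction"):
            value = getattr(self, name)
            if not (0.0 <= float(value) <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        for name in ("hub_target_range", "nonhub_target_range"):
            rng_ = getattr(self, name)
            if (len(rng_) != 2 or rng_[0] < 0 or rng_[1] < rng_[0]):
                raise ConfigurationError(
                    f"{name} must be a nonempty interval (lo, hi) with 0 <= lo <= hi, "
                    f"got {rng_!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")


@dataclass(frozen=True)
class DegreeTable:
    """A degree-frequency table: rows of (k, number of nodes with degree k).

    ``frequency_pct`` is derived (100·frequency/N). When the table represents
    a realized simple graph, Σ k·frequency must be even (handshake lemma);
    :meth:`expand` and :func:`graph_from_degree_table` enforce that.
    """

    rows: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for k, freq in self.rows:
            if k < 0:
                raise ValidationError(f"degree {k} is negative")
            if freq < 1:
                raise ValidationError(f"frequency {freq} for degree {k} is < 1")
            if k in seen:
                raise ValidationError(f"degree {k} appears in more than one row")
            seen.add(k)

    @property
    def n_nodes(self) -> int:
        return sum(freq for _, freq in self.rows)

    @property
    def sum_k_frequency(self) -> int:
        return sum(k * freq for k, freq in self.rows)

    @property
    def n_edges_implied(self) -> int:
        total = self.sum_k_frequency
        if total % 2:
            raise ValidationError(
                f"Σ k·frequency = {total} is odd; not a realizable simple graph")
        return total // 2

    @property
    def mean_degree(self) -> float:
        return self.sum_k_frequency / self.n_nodes

    def frequency_pct(self) -> list[float]:
        n = self.n_nodes
        return [100.0 * freq / n for _, freq in self.rows]

    def expand(self) -> list[int]:
        """The full degree sequence, descending."""
        seq: list[int] = []
        for k, freq in sorted(self.rows, reverse=True):
            seq.extend([k] * freq)
        return seq

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(sorted(self.rows, reverse=True), columns=["k", "frequency"])
        df["frequency_pct"] = [round(p, 2) for p in
                               (100.0 * df["frequency"] / self.n_nodes)]
        return df

    @classmethod
    def from_degrees(cls, degrees: Iterable[int]) -> "DegreeTable":
        counts: dict[int, int] = {}
        for k in degrees:
            counts[int(k)] = counts.get(int(k), 0) + 1
        return cls(tuple(sorted(counts.items(), reverse=True)))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DegreeTable":
        return cls(tuple((int(r.k), int(r.frequency)) for r in df.itertuples()))


# ---------------------------------------------------------------------------
# compound table generation
# ---------------------------------------------------------------------------

def generate_compound_table(config: SimulationConfig) -> pd.DataFrame:
    """Generate ``config.n_compounds`` compound records.

    A ``druglike_fraction`` share (rounded) satisfies all four rule-of-five
    criteria; the remainder each violate at least one, with every criterion
    violated by some record whenever at least four records fail (for fewer
    failing records, each violates all four criteria so coverage still holds).
    Relative abundances are positive and sum to <= 100.
    """
    n = config.n_compounds
    rng = np.random.default_rng(config.seed)
    n_pass = int(round(config.druglike_fraction * n))
    n_fail = n - n_pass

    records = []
    for i in range(n):
        cid = f"C{i + 1:04d}"
        name = f"compound_{i + 1:04d}"
        passing = i < n_pass
        mw = float(rng.uniform(90.0, 480.0))
        hbd = int(rng.integers(0, _HBD_MAX + 1))
        hba = int(rng.integers(0, _HBA_MAX + 1))
        mlogp = float(rng.uniform(-1.0, _MLOGP_MAX))
        if not passing:
            j = i - n_pass
            # which criteria this record violates
            violate = {"mw", "hbd", "hba", "mlogp"} if n_fail < 4 else \
                {("mw", "hbd", "hba", "mlogp")[j % 4]}
            if "mw" in violate:
                mw = float(rng.uniform(_MW_MAX, _MW_MAX + 400.0))
            if "hbd" in violate:
                hbd = int(rng.integers(_HBD_MAX + 1, _HBD_MAX + 6))
            if "hba" in violate:
                hba = int(rng.integers(_HBA_MAX + 1, _HBA_MAX + 8))
            if "mlogp" in violate:
                mlogp = float(rng.uniform(_MLOGP_MAX + 0.1, _MLOGP_MAX + 4.0))
        records.append((cid, name, 0.0, mw, hbd, hba, mlogp))

    df = pd.DataFrame(records, columns=list(COMPOUND_COLUMNS))
    # positive abundances summing to <= 100 (gamma weights scaled to 95%)
    weights = rng.gamma(shape=0.8, scale=1.0, size=n) + 1e-6
    df["abundance_pct"] = np.round(95.0 * weights / weights.sum(), 6)
    return df


# ---------------------------------------------------------------------------
# interaction generation
# ---------------------------------------------------------------------------

def target_ids(n_targets: int) -> list[str]:
    return [f"T{i + 1:04d}" for i in range(n_targets)]


def generate_interactions(compounds: pd.DataFrame,
                          config: SimulationConfig) -> pd.DataFrame:
    """Generate a compound->target edge list with hub structure.

    The first ``round(hub_fraction * n)`` compounds are hubs and draw their
    target count from ``hub_target_range``; the rest draw from
    ``nonhub_target_range``. Target popularity is Zipf-weighted so the
    per-target support distribution is heavy-tailed; when ``n_targets >= 10``
    an enforcement step guarantees at least one target with support < 5 and
    one with support >= 5, so the support filter downstream is exercised.
    """
    if compounds.empty:
        raise ValidationError("compounds table is empty")
    n_targets = config.n_targets
    if config.hub_target_range[1] > n_targets:
        raise ConfigurationError(
            f"hub_target_range {config.hub_target_range} exceeds n_targets={n_targets}")
    if config.nonhub_target_range[1] > n_targets:
        raise ConfigurationError(
            f"nonhub_target_range {config.nonhub_target_range} exceeds "
            f"n_targets={n_targets}")

    rng = np.random.default_rng(config.seed + 1)
    tids = np.asarray(target_ids(n_targets), dtype=object)
    weights = 1.0 / (np.arange(1, n_targets + 1) ** 0.8)
    weights /= weights.sum()

    n_hubs = int(round(config.hub_fraction * len(compounds)))
    rows: list[tuple[str, str]] = []
    for i, cid in enumerate(compounds["compound_id"]):
        lo, hi = (config.hub_target_range if i < n_hubs
                  else config.nonhub_target_range)
        count = int(rng.integers(lo, hi + 1))
        if count == 0:
            continue
        chosen = rng.choice(n_targets, size=count, replace=False, p=weights)
        rows.extend((cid, tids[t]) for t in sorted(chosen))

    table = pd.DataFrame(rows, columns=["compound_id", "target_id"])
    if n_targets >= 10 and not table.empty:
        table = _enforce_support_mix(table, compounds, rng)
    return table.reset_index(drop=True)


def _enforce_support_mix(table: pd.DataFrame, compounds: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Guarantee the generated table has targets both below and at/above the
    default support threshold of 5 distinct compounds."""
    support = table.groupby("target_id")["compound_id"].nunique()
    if (support < 5).sum() == 0:
        # trim the least-supported target down to 4 links
        tid = support.idxmin()
        keep_rows = table[table["target_id"] == tid].index[:4]
        drop_rows = table[table["target_id"] == tid].index[4:]
        table = table.drop(index=drop_rows)
        del keep_rows
    support = table.groupby("target_id")["compound_id"].nunique()
    linked = set(table["compound_id"])  # never create links for isolated compounds
    if len(linked) >= 5 and (support >= 5).sum() == 0 and not support.empty:
        tid = support.idxmax()
        have = set(table.loc[table["target_id"] == tid, "compound_id"])
        extra = [(cid, tid) for cid in compounds["compound_id"]
                 if cid in linked and cid not in have][: 5 - len(have)]
        table = pd.concat(
            [table, pd.DataFrame(extra, columns=["compound_id", "target_id"])],
            ignore_index=True)
    return table


# ---------------------------------------------------------------------------
# pathway set generation
# ---------------------------------------------------------------------------

def generate_pathway_sets(targets: Sequence[str],
                          config: SimulationConfig) -> PathwayCollection:
    """Generate ``config.n_pathways`` pathway membership sets over *targets*.

    One designated dominant pathway (id ``P0001``) contains
    ``ceil(dominant_pathway_coverage * len(targets))`` proteins. The
    remaining pathways draw members with strong weight on a designated hub
    subset (the first ~5% of targets), so hub proteins appear in many sets.
    Every pathway is nonempty.
    """
    targets = list(targets)
    if not targets:
        raise ValidationError("targets collection is empty")
    coverage = config.dominant_pathway_coverage
    if coverage > 1.0:
        raise ConfigurationError(
            f"dominant_pathway_coverage must be <= 1, got {coverage}")
    rng = np.random.default_rng(config.seed + 2)
    n_t = len(targets)
    dominant_size = max(1, math.ceil(coverage * n_t))
    dominant = list(rng.choice(n_t, size=dominant_size, replace=False))

    n_hub_proteins = max(1, round(0.05 * n_t))
    weights = np.ones(n_t)
    weights[:n_hub_proteins] = 20.0
    weights /= weights.sum()

    entries: list[tuple[str, str, list[str]]] = [
        ("P0001", "dominant pathway", [targets[i] for i in sorted(dominant)])
    ]
    max_size = max(2, min(n_t, max(3, n_t // 8)))
    for j in range(2, config.n_pathways + 1):
        size = int(rng.integers(1, max_size + 1)) if n_t > 1 else 1
        members = rng.choice(n_t, size=min(size, n_t), replace=False, p=weights)
        entries.append((f"P{j:04d}", f"pathway {j}",
                        [targets[i] for i in sorted(members)]))
    return PathwayCollection.from_entries(entries)


# ---------------------------------------------------------------------------
# graphs from degree tables (configuration model with rewiring)
# ---------------------------------------------------------------------------

def graph_from_degree_table(table: DegreeTable, seed: int,
                            max_restarts: int = 20) -> nx.Graph:
    """Realize *table* as a simple undirected graph with exactly the given
    degree sequence.

    Uses stub pairing (the configuration model) followed by degree-preserving
    double-edge swaps that remove self-loops and parallel edges; if a pairing
    cannot be repaired within a bounded number of swaps, it is re-drawn with a
    fresh sub-seed. Raises :class:`NonGraphicalSequenceError` when the
    expanded sequence violates the Erdős–Gallai conditions.
    """
    seq = table.expand()
    if sum(seq) % 2:
        raise NonGraphicalSequenceError(
            f"degree sum {sum(seq)} is odd (handshake lemma)")
    if not nx.is_graphical(seq):
        raise NonGraphicalSequenceError(
            "degree sequence fails the Erdős–Gallai graphicality conditions")

    for attempt in range(max_restarts):
        rng = np.random.default_rng((seed, attempt))
        edges = _pair_stubs(seq, rng)
        repaired = _rewire_to_simple(edges, rng, max_sweeps=200)
        if repaired is not None:
            graph = nx.Graph()
            graph.add_nodes_from(range(len(seq)))
            graph.add_edges_from(repaired)
            assert sorted(d for _, d in graph.degree()) == sorted(seq)
            return graph
    raise ComputationError(
        f"could not realize the degree sequence as a simple graph after "
        f"{max_restarts} restarts")


def _pair_stubs(seq: Sequence[int], rng: np.random.Generator
                ) -> list[tuple[int, int]]:
    stubs = np.repeat(np.arange(len(seq)), seq)
    rng.shuffle(stubs)
    return [(int(stubs[i]), int(stubs[i + 1])) for i in range(0, len(stubs), 2)]


def _rewire_to_simple(edges: list[tuple[int, int]], rng: np.random.Generator,
                      max_sweeps: int) -> list[tuple[int, int]] | None:
    """Remove self-loops/parallel edges by double-edge swaps; None on failure."""
    from collections import Counter

    def norm(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u <= v else (v, u)

    counts = Counter(norm(*e) for e in edges)
    m = len(edges)
    for _ in range(max_sweeps):
        bad = [i for i, (u, v) in enumerate(edges)
               if u == v or counts[norm(u, v)] > 1]
        if not bad:
            return edges
        progressed = False
        for i in bad:
            u, v = edges[i]
            if u != v and counts[norm(u, v)] == 1:
                continue  # fixed by an earlier swap this sweep
            for _try in range(50):
                j = int(rng.integers(0, m))
                if j == i:
                    continue
                x, y = edges[j]
                if rng.integers(0, 2):
                    x, y = y, x
                # propose (u,x) and (v,y)
                if u == x or v == y:
                    continue
                if counts[norm(u, x)] > 0 or counts[norm(v, y)] > 0:
                    continue
                counts[norm(u, v)] -= 1
                counts[norm(x, y)] -= 1
                counts[norm(u, x)] += 1
                counts[norm(v, y)] += 1
                edges[i] = (u, x)
                edges[j] = (v, y)
                progressed = True
                break
        if not progressed:
            return None
    bad = [i for i, (u, v) in enumerate(edges)
           if u == v or counts[norm(u, v)] > 1]
    return edges if not bad else None


# ---------------------------------------------------------------------------
# deterministic study-shaped bundle
# ---------------------------------------------------------------------------

@dataclass
class DatasetBundle:
    """One complete synthetic input set for the pipeline."""

    compounds: pd.DataFrame
    interactions: pd.DataFrame
    pathways: PathwayCollection
    description: str = ""
    extras: dict = field(default_factory=dict)


def study_shaped_bundle() -> DatasetBundle:
    """A deterministic dataset with the composition of the bundled essential-oil
    case study
    exactly: 91 compounds (79 drug-like, 44 with targets), 191 targets and 70
    pathways; two hub ingredients named eugenol (106 targets) and geraniol
    (96); a dominant 50-protein pathway whose core subnetwork has 8
    ingredients, 50 proteins and 150 connections; 879 tripartite links in
    total (553 interactions + 326 memberships).

    The bundle represents *post*-collection data: the target-support filter
    was already applied at harvest time, so pipeline runs on it use
    ``min_support=1``.
    """
    tids = target_ids(191)

    # --- compounds: C0001..C0079 drug-like, C0080..C0091 failing one rule each
    records = []
    names = {1: "eugenol", 2: "geraniol", 3: "dihydro-beta-ionol", 4: "beta-ionone"}
    for i in range(1, 92):
        cid = f"C{i:04d}"
        name = names.get(i, f"compound_{i:04d}")
        if i <= 79:
            mw = 120.0 + (i * 37) % 260
            hbd, hba = i % 4, i % 7
            mlogp = round(0.5 + (i % 40) / 10.0, 2)
        else:
            j = i - 80
            mw, hbd, hba, mlogp = 180.0 + 10 * j, j % 3, j % 5, 2.0
            if j % 4 == 0:
                mw = 520.0 + 15 * j
            elif j % 4 == 1:
                hbd = 6 + j % 3
            elif j % 4 == 2:
                hba = 11 + j % 4
            else:
                mlogp = 5.5 + j / 10.0
        abundance = {1: 0.9, 2: 0.6, 3: 12.0, 4: 6.0}.get(i, 0.8)
        records.append((cid, name, abundance, float(mw), int(hbd), int(hba),
                        float(mlogp)))
    compounds = pd.DataFrame(records, columns=list(COMPOUND_COLUMNS))

    # --- interactions: 553 unique pairs over ingredients C0001..C0044
    pairs: list[tuple[str, str]] = []
    # hub 1 (eugenol): dominant targets T1..T47 plus T51..T109 -> k = 106
    pairs += [("C0001", tids[t]) for t in range(0, 47)]
    pairs += [("C0001", tids[t]) for t in range(50, 109)]
    # hub 2 (geraniol): T1..T46 plus T51..T100 -> k = 96
    pairs += [("C0002", tids[t]) for t in range(0, 46)]
    pairs += [("C0002", tids[t]) for t in range(50, 100)]
    # six more core ingredients contribute 7 edges into the dominant targets
    pairs += [("C0003", tids[47]), ("C0003", tids[48])]
    pairs += [("C0004", tids[49]), ("C0005", tids[0]), ("C0006", tids[1]),
              ("C0007", tids[2]), ("C0008", tids[3])]
    # remaining 36 ingredients link only outside the dominant set (T51..T191)
    seen = set(pairs)
    for t in range(109, 191):  # cover every remaining target once
        pair = (f"C{9 + (t - 109) % 36:04d}", tids[t])
        pairs.append(pair)
        seen.add(pair)
    added, k = 0, 0
    while added < 262:  # fill to 553 interaction rows
        ci = k % 36
        ti = 50 + ((k * 7 + ci * 11) % 141)
        pair = (f"C{9 + ci:04d}", tids[ti])
        k += 1
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
        added += 1
    interactions = pd.DataFrame(pairs, columns=["compound_id", "target_id"])
    assert len(interactions) == 553
    assert interactions["compound_id"].nunique() == 44

    # --- pathways: dominant P0001 (50 members) + 69 pathways of 4 members
    entries = [("P0001", "neuroactive ligand-receptor interaction",
                [tids[t] for t in range(0, 50)])]
    for j in range(2, 71):
        members = {tids[0] if j % 2 == 0 else tids[1]}
        i = 0
        while len(members) < 4:
            members.add(tids[(j * 13 + i * 29) % 191])
            i += 1
        entries.append((f"P{j:04d}", f"pathway {j}", sorted(members)))
    pathways = PathwayCollection.from_entries(entries)
    n_memberships = sum(len(p.members) for p in pathways)
    assert len(interactions) + n_memberships == 879

    return DatasetBundle(
        compounds=compounds,
        interactions=interactions,
        pathways=pathways,
        description="deterministic study-shaped bundle (synthetic)",
    )


def simulate_bundle(config: SimulationConfig) -> DatasetBundle:
    """Generate a full random dataset (compounds, interactions, pathways)
    from one config; drug-like labels, hub structure and the dominant
    pathway are planted per the config."""
    compounds = generate_compound_table(config)
    interactions = generate_interactions(compounds, config)
    observed = sorted(set(interactions["target_id"])) if len(interactions) \
        else target_ids(config.n_targets)
    pathways = generate_pathway_sets(observed, config)
    return DatasetBundle(compounds, interactions, pathways,
                         description=f"simulated bundle (seed={config.seed})")


# ---------------------------------------------------------------------------
# built-in fixtures
# ---------------------------------------------------------------------------

_FIXTURE_NAMES = ("ofte_table1", "ofte_sizes", "toy_triangle", "toy_star5",
                  "toy_path3", "toy_twopathways")


def _data_path(filename: str):
    return resources.files("netpharm").joinpath("data", filename)


def builtin_fixture(name: str):
    """Return a packaged fixture by name.

    * ``ofte_table1`` — the transcribed degree-frequency table of the
      case study's 142-node protein association network (:class:`DegreeTable`)
    * ``ofte_sizes`` — the printed network compositions (dict)
    * ``toy_triangle`` / ``toy_star5`` / ``toy_path3`` — hand-checkable graphs
    * ``toy_twopathways`` — a two-set :class:`PathwayCollection`
    """
    if name not in _FIXTURE_NAMES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {', '.join(_FIXTURE_NAMES)}")
    if name == "ofte_table1":
        with resources.as_file(_data_path("ofte_table1.tsv")) as p:
            df = pd.read_csv(p, sep="\t")
        return DegreeTable.from_frame(df)
    if name == "ofte_sizes":
        return json.loads(_data_path("ofte_sizes.json").read_text(encoding="utf-8"))
    if name == "toy_twopathways":
        with resources.as_file(_data_path("toy_twopathways.gmt")) as p:
            return read_gmt(p)
    with resources.as_file(_data_path(f"{name}.net")) as p:
        return read_pajek(p)
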