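"""Synthetic multi-condition time-course expression data with planted structure.

The generator emulates a designed expression study: several treatment
conditions crossed with time points, a few replicates per cell, and a
small untreated baseline-control group. Genes fall into coexpression
modules driven by latent per-module profiles over the condition x time
grid; *bridge* genes mix the profiles of two (or more) modules and are the
planted bottlenecks — they correlate with both modules and become the
inter-module connectors of the inferred network. Background genes are pure
noise around a flat baseline. Optional duplicate probesets replicate a
gene with independent noise, mimicking arrays where several probesets
interrogate one gene.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so every artifact (matrix, design, annotation, gene sets,
knockdown responses) is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .expr_data import ExpressionMatrix, ProbeAnnotation, SampleDesign, GeneSetCollection
from .topology import BottleneckRanking

BASELINE_LEVEL = 8.0  # flat log2 baseline around which profiles move

#: CLR z threshold playing the role of the reference setting of 5.0 on
#: generator-scale networks (a few hundred probes): it sits just above the
#: empirical null support of the CLR score — scores of background and
#: cross-module pairs stay below ~1 at these sample sizes — so retained
#: edges are overwhelmingly planted structure.
DEFAULT_SYNTHETIC_Z = 1.0


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults emulate a preconditioning-style study
    (5 treatments x 5 time points x 4 replicates plus 6 untreated controls)."""

    n_modules: int = 5
    genes_per_module: int = 40
    n_bridge_genes: int = 6
    n_background_genes: int = 20
    conditions: tuple[str, ...] = ("trtA", "trtB", "trtC", "trtD", "trtE")
    timepoints: tuple[str, ...] = ("t03h", "t24h", "t72h", "post03h", "post24h")
    replicates: int = 4
    n_baseline_controls: int = 6
    noise_sd: float = 0.4
    profile_sd: float = 1.0  # sd of each latent profile across the grid (log2); 0 = no signal
    bridge_n_modules: int = 2  # modules mixed per bridge, equal weights
    duplicate_probe_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_modules, self.genes_per_module, self.n_bridge_genes,
               self.n_background_genes, self.replicates) < 0:
            raise ValueError("all counts must be >= 0")
        if self.n_bridge_genes > 0 and self.n_modules < 2:
            raise ValueError("bridges need >= 2 modules to mix")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.duplicate_probe_fraction <= 1:
            raise ValueError("duplicate_probe_fraction must lie in [0, 1]")
        if self.bridge_n_modules < 2:
            raise ValueError("bridges mix >= 2 modules")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure: gene -> module label, bridge mixings, latent profiles."""

    gene_module: dict  # gene -> "module_<m>" | "bridge" | "background"
    bridge_mixing: dict  # bridge gene -> {module label: weight}
    profiles: np.ndarray  # n_modules x (|conditions| * |timepoints|)
    probe_gene: dict  # probe_id -> gene
    params: SyntheticParams

    @property
    def bridge_genes(self) -> frozenset:
        return frozenset(self.bridge_mixing)

    def module_members(self, m: int) -> list[str]:
        label = f"module_{m}"
        return sorted(g for g, lab in self.gene_module.items() if lab == label)

    def to_json(self) -> str:
        d = {
            "gene_module": self.gene_module,
            "bridge_mixing": self.bridge_mixing,
            "profiles": np.asarray(self.profiles).tolist(),
            "probe_gene": self.probe_gene,
            "params": asdict(self.params),
        }
        return json.dumps(d, indent=2)


#: minimum log2 span enforced on every planted signal (modules and bridge
#: mixtures) so the two-fold-change filter is always exercisable under
#: replicate noise.
AMPLITUDE_FLOOR = 2.5


def _module_profiles(
    rng: np.random.Generator,
    n_modules: int,
    n_conditions: int,
    n_timepoints: int,
    profile_sd: float,
) -> np.ndarray:
    """Latent module profiles over the condition x time grid.

    Each raw profile is an additive surface: a random walk over conditions
    plus a random walk over time points, mirroring how treatment and time
    responses combine in designed expression studies (and keeping planted
    signal inside the subspace a condition+time main-effects model tests).
    Raw surfaces are then QR-orthogonalized against each other and against
    the constant vector, so planted modules are genuinely distinct,
    uncorrelated coexpression groups (independent walks on a short grid can
    be strongly correlated by chance, which would merge modules), and each
    profile is scaled to standard deviation ``profile_sd`` across the grid.
    Equal sd makes an equal-weight bridge mixture correlate equally with
    both of its modules.
    """
    n_points = n_conditions * n_timepoints
    if n_modules == 0 or profile_sd == 0:
        return np.zeros((n_modules, n_points))
    additive_dim = (n_conditions - 1) + (n_timepoints - 1)
    if n_modules > additive_dim:
        raise ValueError(
            f"{n_modules} modules exceed the {additive_dim}-dimensional "
            "additive condition+time subspace; enlarge the design"
        )
    surfaces = np.empty((n_points, n_modules))
    for m in range(n_modules):
        cond_walk = np.cumsum(rng.normal(size=n_conditions))
        time_walk = np.cumsum(rng.normal(size=n_timepoints))
        surfaces[:, m] = np.add.outer(cond_walk, time_walk).ravel()
    basis = np.column_stack([np.ones(n_points), surfaces])
    Q, R = np.linalg.qr(basis)
    Q = Q * np.sign(np.diag(R))  # fix sign convention for reproducibility
    profiles = np.empty((n_modules, n_points))
    for m in range(n_modules):
        col = Q[:, m + 1]  # orthogonal to constant => centered & uncorrelated
        sd = col.std()
        profiles[m] = col / sd * profile_sd if sd > 0 else 0.0
    return profiles


def _enforce_span(signal: np.ndarray, floor: float = AMPLITUDE_FLOOR) -> np.ndarray:
    """Rescale a nonzero signal so its span reaches the amplitude floor.

    Applied to bridge mixtures: averaging two module profiles shrinks the
    span, and a planted bottleneck that cannot pass the fold-change filter
    would be unrecoverable by construction. Rescaling leaves all
    correlations unchanged.
    """
    span = signal.max() - signal.min()
    if span == 0 or span >= floor:
        return signal
    return signal / span * floor


def _bridge_module_pairs(n_bridges: int, n_modules: int, k: int) -> list[tuple[int, ...]]:
    """Module tuples mixed by each bridge: a ring through all modules first,
    then chords, so pairs are distinct as long as the design permits and each
    bridge is the sole planted connector of its module pair."""
    pairs: list[tuple[int, ...]] = []
    seen = set()
    j = 0
    step = 1
    while len(pairs) < n_bridges:
        mods = tuple(sorted({(j + i * step) % n_modules for i in range(k)}))
        if len(mods) == k and mods not in seen:
            seen.add(mods)
            pairs.append(mods)
        j += 1
        if j >= n_modules:
            j = 0
            step += 1
            if step >= n_modules:  # all tuples exhausted; allow repeats
                seen.clear()
    return pairs


def generate_dataset(
    params: SyntheticParams,
) -> tuple[ExpressionMatrix, SampleDesign, ProbeAnnotation, SyntheticTruth]:
    """Generate one expression dataset plus design, annotation, and truth."""
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rng_profile, rng_noise, _, rng_dup = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    n_points = len(params.conditions) * len(params.timepoints)
    profiles = _module_profiles(
        rng_profile,
        params.n_modules,
        len(params.conditions),
        len(params.timepoints),
        params.profile_sd,
    )

    # planted gene table (names deterministic in the parameters, so datasets
    # generated with different seeds share bridge identities)
    gene_module: dict[str, str] = {}
    bridge_mixing: dict[str, dict] = {}
    gene_signal: dict[str, np.ndarray] = {}
    for m in range(params.n_modules):
        for i in range(params.genes_per_module):
            g = f"M{m}G{i:03d}"
            gene_module[g] = f"module_{m}"
            gene_signal[g] = profiles[m]
    pairs = _bridge_module_pairs(
        params.n_bridge_genes, params.n_modules, params.bridge_n_modules
    ) if params.n_bridge_genes else []
    for j, mods in enumerate(pairs):
        g = "BR{}_{}".format(j, "_".join(str(m) for m in mods))
        w = 1.0 / len(mods)
        gene_module[g] = "bridge"
        bridge_mixing[g] = {f"module_{m}": w for m in mods}
        mix = sum(w * profiles[m] for m in mods)
        gene_signal[g] = _enforce_span(mix) if params.profile_sd > 0 else mix
    for i in range(params.n_background_genes):
        g = f"BG{i:03d}"
        gene_module[g] = "background"
        gene_signal[g] = np.zeros(n_points)

    genes = sorted(gene_module)
    # duplicate probesets: first ceil(fraction * n_genes) genes (deterministic
    # choice by shuffled order under the duplication stream) get a second probe
    n_dup = int(round(params.duplicate_probe_fraction * len(genes)))
    dup_genes = set(
        rng_dup.choice(np.array(genes), size=n_dup, replace=False)
    ) if n_dup else set()
    probe_gene: dict[str, str] = {}
    for g in genes:
        probe_gene[f"{g}_p1"] = g
        if g in dup_genes:
            probe_gene[f"{g}_p2"] = g
    probes = sorted(probe_gene)

    # samples: full factorial + baseline controls
    sample_ids, design_rows = [], []
    grid_index: dict[str, int] = {}
    for ci, cond in enumerate(params.conditions):
        for ti, tp in enumerate(params.timepoints):
            for r in range(1, params.replicates + 1):
                sid = f"{cond}_{tp}_r{r}"
                sample_ids.append(sid)
                design_rows.append((sid, cond, tp, r, False))
                grid_index[sid] = ci * len(params.timepoints) + ti
    for r in range(1, params.n_baseline_controls + 1):
        sid = f"control_r{r}"
        sample_ids.append(sid)
        design_rows.append((sid, "control", "baseline", r, True))

    values = np.empty((len(probes), len(sample_ids)))
    for pi, probe in enumerate(probes):
        sig = gene_signal[probe_gene[probe]]
        mean = np.array(
            [BASELINE_LEVEL + (sig[grid_index[s]] if s in grid_index else 0.0)
             for s in sample_ids]
        )
        values[pi] = mean + rng_noise.normal(scale=params.noise_sd, size=len(sample_ids))
    values = np.round(values, 10)  # match serialization precision for round-trips

    matrix = ExpressionMatrix(tuple(probes), tuple(sample_ids), values)
    design = SampleDesign(
        pd.DataFrame(
            design_rows,
            columns=["sample_id", "condition", "time", "replicate", "is_baseline_control"],
        ).set_index("sample_id")
    )
    annot = ProbeAnnotation(dict(probe_gene))
    truth = SyntheticTruth(gene_module, bridge_mixing, profiles, probe_gene, params)
    return matrix, design, annot, truth


def generate_gene_sets(truth: SyntheticTruth, n_decoys: int = 10) -> GeneSetCollection:
    """One term per planted module (bridges excluded) plus size-matched decoys.

    Decoy members are drawn uniformly from the full gene universe; decoy
    sizes cycle through the module sizes so the size distribution matches.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(truth.params.seed).spawn(5)[-1]
    )
    terms: dict[str, tuple[str, frozenset]] = {}
    module_sizes = []
    for m in range(truth.params.n_modules):
        members = frozenset(truth.module_members(m))
        if members:
            terms[f"MODULE_{m}"] = (f"planted module {m}", members)
            module_sizes.append(len(members))
    universe = np.array(sorted(truth.gene_module))
    for d in range(n_decoys):
        size = module_sizes[d % len(module_sizes)] if module_sizes else 5
        members = frozenset(rng.choice(universe, size=min(size, len(universe)), replace=False))
        terms[f"DECOY_{d}"] = (f"random decoy set {d}", members)
    return GeneSetCollection(terms)


def generate_knockdown_matrix(
    truth: SyntheticTruth,
    n_regulators: int = 125,
    seed: int = 0,
    regulator_prob: float = 0.3,
    effect_sd: float = 1.0,
) -> pd.DataFrame:
    """Gene x regulator-knockdown response matrix for the coherence test.

    Each module is assigned a random subset of regulators (each regulator
    hits a module with probability ``regulator_prob``); genes of a module
    share the module's latent effect for each of its regulators, plus
    independent noise. Bridge genes average their modules' effects;
    background genes are noise only.
    """
    if n_regulators < 1:
        raise ValueError("need >= 1 regulator")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_mod = truth.params.n_modules
    assigned = rng.random((n_mod, n_regulators)) < regulator_prob
    effects = np.where(assigned, rng.normal(scale=effect_sd, size=(n_mod, n_regulators)), 0.0)
    genes = sorted(truth.gene_module)
    rows = np.empty((len(genes), n_regulators))
    for gi, g in enumerate(genes):
        label = truth.gene_module[g]
        if label.startswith("module_"):
            base = effects[int(label.split("_")[1])]
        elif label == "bridge":
            base = sum(
                w * effects[int(mlab.split("_")[1])]
                for mlab, w in truth.bridge_mixing[g].items()
            )
        else:
            base = np.zeros(n_regulators)
        rows[gi] = base + rng.normal(scale=truth.params.noise_sd, size=n_regulators)
    return pd.DataFrame(
        rows, index=genes, columns=[f"kd_{i:03d}" for i in range(n_regulators)]
    )


def evaluate_recovery(
    ranking: BottleneckRanking, truth: SyntheticTruth
) -> tuple[float, float]:
    """Gene-level precision and recall of planted bridges among flagged bottlenecks."""
    ranked_genes = {truth.probe_gene.get(p) for p in ranking.rank}
    ranked_genes.discard(None)
    if not ranked_genes & set(truth.gene_module):
        raise ValueError("ranking and truth share no genes")
    flagged = {truth.probe_gene[p] for p in ranking.bottleneck_nodes
               if p in truth.probe_gene}
    bridges = truth.bridge_genes
    tp = len(flagged & bridges)
    precision = tp / len(flagged) if flagged else 0.0
    recall = tp / len(bridges) if bridges else 0.0
    return precision, recall
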