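"""Ground-truthed synthetic Drop-seq cohort generator.

Emulates the statistical structure of a two-arm single-cell tumor cohort:
discrete stromal populations, a multi-tier differentiation continuum with
cell-cycle structure, doublets, ambient RNA, mitochondrial stress, a
foreign-species spike-in and a Cre-activated lineage reporter, with
per-animal replicate structure and configurable treatment effects
(population depletion, differentiation shift, and an arm-dependent sign of
the coupling between a designated regulator/target gene pair).

Counts are drawn by multinomial allocation of a negative-binomially drawn
library size over a per-cell gene program mixed with an ambient pool and a
mitochondrial component.  Every emitted barcode carries a ground-truth
record (population, pseudotime, phase, doublet parents, species, lineage)
for recovery testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import CountMatrix
from .resources import load_cell_cycle_genes

logger = logging.getLogger(__name__)

__all__ = [
    "Population",
    "TrajectoryPopulation",
    "TreatmentEffect",
    "CouplingSpec",
    "SimulationConfig",
    "EffectiveArm",
    "InvalidConfigError",
    "simulate_cohort",
    "inject_doublets",
    "make_hybrids",
    "apply_treatment_effect",
    "default_config",
    "TRUTH_COLUMNS",
]

#: Ground-truth schema: one row per emitted barcode.
TRUTH_COLUMNS = [
    "population", "animal", "arm", "pseudotime", "tier", "phase",
    "is_doublet", "parent1", "parent2", "species", "lineage",
    "library_size", "mito_fraction",
]

PHASES = ("G1", "S", "G2", "M")


class InvalidConfigError(ValueError):
    pass


def _normalize_program(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise InvalidConfigError("program weights must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise InvalidConfigError("program has zero total weight")
    return p / total


@dataclass
class Population:
    """A discrete population with a fixed expression program over all genes."""

    name: str
    n_cells_per_animal: int
    program: np.ndarray
    lineage_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.program = _normalize_program(self.program)


@dataclass
class TrajectoryPopulation:
    """A differentiation continuum: programs interpolate early -> late with
    pseudotime drawn from a three-tier Beta mixture (density troughs between
    tiers make the continuum resolvable into clusters)."""

    name: str
    n_cells_per_animal: int
    early_program: np.ndarray
    late_program: np.ndarray
    lineage_fraction: float = 0.0
    cycling_fraction: float = 0.7
    tier_weights: tuple[float, float, float] = (0.4, 0.35, 0.25)
    tier_beta: tuple[float, float] = (3.0, 3.0)
    tier_gap: float = 0.3  # fraction of each tier's span left empty at the edges

    def __post_init__(self) -> None:
        self.early_program = _normalize_program(self.early_program)
        self.late_program = _normalize_program(self.late_program)


@dataclass
class CouplingSpec:
    """Latent pathway-activity coupling in trajectory cells.

    A per-cell latent z ~ N(0,1) scales the regulator by exp(strength * z)
    and the target by exp(sign * strength * z), with the sign set per arm.
    The same latent also modulates a block of pathway ``module_genes`` by
    exp(module_strength * z) in every arm, so pathway activity is part of
    the observable cell state (neighboring cells share it) rather than
    isolated two-gene noise."""

    regulator: str
    target: str
    strength: float = 0.7
    module_genes: list[str] = field(default_factory=list)
    module_strength: float = 0.6


@dataclass
class TreatmentEffect:
    population_multipliers: dict[str, float] = field(default_factory=dict)
    tier_shift: float = 0.0
    coupling_sign: int = 1


@dataclass
class EffectiveArm:
    """Per-arm resolved sampling plan from :func:`apply_treatment_effect`."""

    arm: str
    fractions: dict[str, float]
    tier_weights: dict[str, tuple[float, float, float]]
    coupling_sign: int


@dataclass
class SimulationConfig:
    genes: pd.DataFrame
    populations: list[Population]
    trajectories: list[TrajectoryPopulation] = field(default_factory=list)
    n_animals_per_arm: int = 5
    arms: tuple[str, ...] = ("vehicle", "treated")
    effects: dict[str, TreatmentEffect] = field(default_factory=dict)
    doublet_rate: float = 0.05
    ambient_rate: float = 0.02
    mito_beta: tuple[float, float] = (2.5, 60.0)
    mito_stress_rate: float = 0.03
    mito_stress_beta: tuple[float, float] = (40.0, 10.0)
    spikein_rate: float = 0.04
    chimera_rate: float = 0.02
    human_program: np.ndarray | None = None
    library_size_mean: float = 2500.0
    library_dispersion: float = 0.08
    animal_effect_sd: float = 0.08
    cell_noise_sd: float = 0.35  # per-cell, per-gene lognormal program noise (BCV)
    phase_gene_sets: dict[str, list[str]] = field(default_factory=dict)
    phase_boost: float = 4e-4
    coupling: CouplingSpec | None = None
    lineage_weight: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if len(self.genes) == 0:
            raise InvalidConfigError("gene table is empty")
        if not self.populations and not self.trajectories:
            raise InvalidConfigError("no populations configured")
        for r, name in [
            (self.doublet_rate, "doublet_rate"), (self.ambient_rate, "ambient_rate"),
            (self.spikein_rate, "spikein_rate"), (self.chimera_rate, "chimera_rate"),
            (self.mito_stress_rate, "mito_stress_rate"),
        ]:
            if not (0 <= r < 1):
                raise InvalidConfigError(f"{name} must lie in [0, 1)")
        for pop in self.populations:
            if len(pop.program) != len(self.genes):
                raise InvalidConfigError(f"program length mismatch for {pop.name}")
        for arm in self.effects:
            if arm not in self.arms:
                raise InvalidConfigError(f"effect declared for unknown arm {arm!r}")

    @property
    def all_population_names(self) -> list[str]:
        return [p.name for p in self.populations] + [t.name for t in self.trajectories]


# ---------------------------------------------------------------------------
# treatment effects
# ---------------------------------------------------------------------------


def apply_treatment_effect(config: SimulationConfig, arm: str) -> EffectiveArm:
    """Resolve the per-arm sampling plan.

    Population fractions are the configured per-animal cell counts rescaled
    by the arm's multipliers and renormalized; trajectory tier weights are
    reweighted by ``exp(tier_shift * tier_index)`` (a positive shift moves
    mass toward the differentiated end); the regulator/target coupling sign
    is taken from the arm's effect.
    """
    if arm not in config.arms:
        raise InvalidConfigError(f"unknown arm {arm!r}; declared arms: {config.arms}")
    effect = config.effects.get(arm, TreatmentEffect())
    names = config.all_population_names
    base = np.array(
        [p.n_cells_per_animal for p in config.populations]
        + [t.n_cells_per_animal for t in config.trajectories],
        dtype=float,
    )
    mult = np.array([effect.population_multipliers.get(n, 1.0) for n in names])
    scaled = base * mult
    if base.sum() == 0:
        fractions = dict(zip(names, np.zeros(len(names))))
    elif scaled.sum() <= 0:
        raise InvalidConfigError(f"arm {arm!r} multipliers remove every population")
    else:
        fractions = dict(zip(names, scaled / scaled.sum()))
    tier_weights = {}
    for t in config.trajectories:
        w = np.asarray(t.tier_weights, dtype=float) * np.exp(
            effect.tier_shift * np.arange(3)
        )
        tier_weights[t.name] = tuple(w / w.sum())
    return EffectiveArm(arm, fractions, tier_weights, effect.coupling_sign)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a full two-arm cohort; returns (counts, ground truth).

    Reproducible: the same config and seed yield bit-identical matrices.
    Doublets are injected at ``config.doublet_rate`` after all singlets are
    drawn (mouse singlets only; cross-species co-encapsulation is modeled
    separately through ``chimera_rate``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    G = len(config.genes)
    gene_index = config.genes.index

    mito_mask = config.genes["mito"].to_numpy(bool)
    mito_profile = np.zeros(G)
    if mito_mask.any():
        mito_profile[mito_mask] = 1.0 / mito_mask.sum()

    phase_idx = {
        ph: gene_index.get_indexer([g for g in genes if g in gene_index])
        for ph, genes in config.phase_gene_sets.items()
    }

    yfp_idx = np.flatnonzero(config.genes["transgene"].to_numpy(bool))
    coup = config.coupling
    if coup is not None:
        reg_i = gene_index.get_loc(coup.regulator)
        tgt_i = gene_index.get_loc(coup.target)
        module_idx = gene_index.get_indexer(
            [g for g in coup.module_genes if g in gene_index]
        )

    n_per_animal = sum(p.n_cells_per_animal for p in config.populations) + sum(
        t.n_cells_per_animal for t in config.trajectories
    )

    blocks: list[sp.csr_matrix] = []
    truth_rows: list[dict] = []
    barcode_ids: list[str] = []

    pop_by_name: dict[str, Population | TrajectoryPopulation] = {
        p.name: p for p in config.populations
    }
    pop_by_name.update({t.name: t for t in config.trajectories})

    for arm in config.arms:
        eff = apply_treatment_effect(config, arm)
        # ambient pool: fraction-weighted mean of mouse population programs
        ambient = np.zeros(G)
        for name, frac in eff.fractions.items():
            p = pop_by_name[name]
            prog = (
                p.program
                if isinstance(p, Population)
                else 0.5 * (p.early_program + p.late_program)
            )
            ambient += frac * prog
        if ambient.sum() > 0:
            ambient = ambient / ambient.sum()

        for a in range(1, config.n_animals_per_arm + 1):
            animal = f"{arm}{a}"
            lib_mean = config.library_size_mean * rng.lognormal(
                0.0, config.animal_effect_sd
            )
            if n_per_animal > 0:
                counts_per_pop = rng.multinomial(
                    n_per_animal, [eff.fractions[n] for n in eff.fractions]
                )
            else:
                counts_per_pop = np.zeros(len(eff.fractions), dtype=int)
            for name, n_cells in zip(eff.fractions, counts_per_pop):
                if n_cells == 0:
                    continue
                p = pop_by_name[name]
                if isinstance(p, Population):
                    block, rows = _draw_discrete(
                        rng, p, int(n_cells), config, lib_mean, ambient,
                        mito_profile, yfp_idx, animal, arm,
                    )
                else:
                    block, rows = _draw_trajectory(
                        rng, p, int(n_cells), config, eff, lib_mean, ambient,
                        mito_profile, phase_idx, yfp_idx,
                        (reg_i, tgt_i, module_idx) if coup is not None else None,
                        animal, arm,
                    )
                blocks.append(block)
                truth_rows.extend(rows)
            # foreign-species spike-in + chimeric barcodes
            n_spike = int(round(config.spikein_rate * n_per_animal))
            n_chim = int(round(config.chimera_rate * n_per_animal))
            if config.human_program is not None and (n_spike or n_chim):
                block, rows = _draw_spikeins(
                    rng, config, n_spike, n_chim, lib_mean, ambient, animal, arm
                )
                blocks.append(block)
                truth_rows.extend(rows)

    if not truth_rows:
        counts = sp.csr_matrix((G, 0), dtype=np.int64)
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        truth.index.name = "barcode"
        barcodes = pd.DataFrame(columns=["animal", "arm"])
        barcodes.index.name = "barcode"
        return CountMatrix(counts, config.genes.copy(), barcodes), truth

    counts = sp.vstack(blocks).T.tocsr()  # blocks are cells x genes
    truth = pd.DataFrame(truth_rows)
    per_animal_seq: dict[str, int] = {}
    for row in truth_rows:
        k = per_animal_seq.get(row["animal"], 0)
        barcode_ids.append(f"{row['animal']}_{k:05d}")
        per_animal_seq[row["animal"]] = k + 1
    truth.index = pd.Index(barcode_ids, name="barcode")
    barcodes = truth[["animal", "arm"]].copy()
    matrix = CountMatrix(counts, config.genes.copy(), barcodes)

    if config.doublet_rate > 0:
        matrix, truth = inject_doublets(
            matrix, truth, config.doublet_rate, seed=int(rng.integers(2**31))
        )
    return matrix, truth


def _mix(prog, ambient_rate, mito_f, ambient, mito_profile):
    """Per-cell final sampling probabilities: program + ambient + mito."""
    base = (1.0 - ambient_rate - mito_f)[:, None] * prog
    base += ambient_rate * ambient[None, :]
    base += mito_f[:, None] * mito_profile[None, :]
    return base / base.sum(axis=1, keepdims=True)


def _draw_mito_fractions(rng, config, n):
    stressed = rng.random(n) < config.mito_stress_rate
    f = rng.beta(*config.mito_beta, size=n)
    f[stressed] = rng.beta(*config.mito_stress_beta, size=stressed.sum())
    return f, stressed


def _sample_counts(rng, libs, probs):
    out = np.empty(probs.shape, dtype=np.int64)
    for i in range(probs.shape[0]):
        out[i] = rng.multinomial(libs[i], probs[i])
    return sp.csr_matrix(out)


def _draw_libraries(rng, config, lib_mean, n):
    if config.library_dispersion == 0:
        return np.full(n, int(round(lib_mean)), dtype=np.int64)
    r = 1.0 / config.library_dispersion
    return rng.negative_binomial(r, r / (r + lib_mean), size=n) + 1


def _draw_discrete(rng, pop, n, config, lib_mean, ambient, mito_profile,
                   yfp_idx, animal, arm):
    libs = _draw_libraries(rng, config, lib_mean, n)
    mito_f, _ = _draw_mito_fractions(rng, config, n)
    lineage = rng.random(n) < pop.lineage_fraction
    prog = np.tile(pop.program, (n, 1))
    if config.cell_noise_sd > 0:
        prog = prog * np.exp(
            rng.normal(0.0, config.cell_noise_sd, size=prog.shape)
        )
    if lineage.any() and len(yfp_idx):
        prog[np.ix_(lineage, yfp_idx)] += config.lineage_weight
        prog /= prog.sum(axis=1, keepdims=True)
    probs = _mix(prog, config.ambient_rate, mito_f, ambient, mito_profile)
    block = _sample_counts(rng, libs, probs)
    rows = [
        dict(
            population=pop.name, animal=animal, arm=arm, pseudotime=np.nan,
            tier=-1, phase="low", is_doublet=False, parent1="", parent2="",
            species="mouse", lineage=bool(lineage[i]),
            library_size=int(libs[i]), mito_fraction=float(mito_f[i]),
        )
        for i in range(n)
    ]
    return block, rows


def _draw_trajectory(rng, traj, n, config, eff, lib_mean, ambient, mito_profile,
                     phase_idx, yfp_idx, coup_idx, animal, arm):
    libs = _draw_libraries(rng, config, lib_mean, n)
    mito_f, _ = _draw_mito_fractions(rng, config, n)
    tiers = rng.choice(3, size=n, p=eff.tier_weights[traj.name])
    within = traj.tier_gap / 2 + (1 - traj.tier_gap) * rng.beta(*traj.tier_beta, size=n)
    u = (tiers + within) / 3.0
    prog = (1.0 - u)[:, None] * traj.early_program + u[:, None] * traj.late_program
    if config.cell_noise_sd > 0:
        prog = prog * np.exp(
            rng.normal(0.0, config.cell_noise_sd, size=prog.shape)
        )

    lineage = rng.random(n) < traj.lineage_fraction
    if lineage.any() and len(yfp_idx):
        prog[np.ix_(lineage, yfp_idx)] += config.lineage_weight

    # cycling probability declines along the trajectory
    cycling = rng.random(n) < traj.cycling_fraction * (1.0 - u)
    phases = np.array(["low"] * n, dtype=object)
    if phase_idx:
        names = list(phase_idx)
        draw = rng.integers(len(names), size=n)
        for i in np.flatnonzero(cycling):
            ph = names[draw[i]]
            phases[i] = ph
            idx = phase_idx[ph]
            if len(idx):
                prog[i, idx] += config.phase_boost

    if coup_idx is not None and config.coupling is not None:
        reg_i, tgt_i, module_idx = coup_idx
        z = rng.standard_normal(n)
        s = config.coupling.strength
        prog[:, reg_i] *= np.exp(s * z)
        prog[:, tgt_i] *= np.exp(eff.coupling_sign * s * z)
        if len(module_idx):
            prog[:, module_idx] *= np.exp(config.coupling.module_strength * z)[:, None]

    prog /= prog.sum(axis=1, keepdims=True)
    probs = _mix(prog, config.ambient_rate, mito_f, ambient, mito_profile)
    block = _sample_counts(rng, libs, probs)
    rows = [
        dict(
            population=traj.name, animal=animal, arm=arm,
            pseudotime=float(u[i]), tier=int(tiers[i]), phase=str(phases[i]),
            is_doublet=False, parent1="", parent2="", species="mouse",
            lineage=bool(lineage[i]), library_size=int(libs[i]),
            mito_fraction=float(mito_f[i]),
        )
        for i in range(n)
    ]
    return block, rows


def _draw_spikeins(rng, config, n_spike, n_chim, lib_mean, ambient, animal, arm):
    G = len(config.genes)
    human = _normalize_program(config.human_program)
    rows, progs = [], []
    for _ in range(n_spike):
        progs.append(0.985 * human + 0.015 * ambient)
        rows.append(dict(
            population="spikein", animal=animal, arm=arm, pseudotime=np.nan,
            tier=-1, phase="low", is_doublet=False, parent1="", parent2="",
            species="human", lineage=False, library_size=0, mito_fraction=0.0,
        ))
    for _ in range(n_chim):
        f = rng.uniform(0.2, 0.8)  # mouse fraction: always fails >0.9 purity
        progs.append(f * ambient + (1 - f) * human)
        rows.append(dict(
            population="chimera", animal=animal, arm=arm, pseudotime=np.nan,
            tier=-1, phase="low", is_doublet=False, parent1="", parent2="",
            species="chimeric", lineage=False, library_size=0, mito_fraction=0.0,
        ))
    n = len(rows)
    if n == 0:
        return sp.csr_matrix((0, G), dtype=np.int64), rows
    libs = _draw_libraries(rng, config, lib_mean, n)
    probs = np.vstack(progs)
    probs /= probs.sum(axis=1, keepdims=True)
    block = _sample_counts(rng, libs, probs)
    for i, row in enumerate(rows):
        row["library_size"] = int(libs[i])
    return block, rows


# ---------------------------------------------------------------------------
# doublets
# ---------------------------------------------------------------------------


def inject_doublets(
    matrix: CountMatrix, truth: pd.DataFrame, rate: float, seed: int
) -> tuple[CountMatrix, pd.DataFrame]:
    """Append ``floor(rate * n_singlets)`` doublet barcodes per animal.

    Each doublet is the gene-wise sum of two distinct randomly paired mouse
    singlet barcodes from the same animal (a cell is never paired with
    itself).  Animals with fewer than two eligible singlets are skipped with
    a warning.
    """
    if not (0 <= rate < 1):
        raise InvalidConfigError("doublet rate must lie in [0, 1)")
    if rate == 0 or matrix.n_barcodes == 0:
        return matrix, truth
    rng = np.random.default_rng(seed)
    new_cols, new_rows, new_ids = [], [], []
    for animal, group in truth.groupby("animal", sort=False):
        singlets = group.index[(~group["is_doublet"]) & (group["species"] == "mouse")]
        n_d = int(np.floor(rate * len(singlets)))
        if len(singlets) < 2:
            if n_d:
                logger.warning("animal %s has <2 singlets; skipping doublets", animal)
            continue
        pos = matrix.barcodes.index.get_indexer(singlets)
        for k in range(n_d):
            i, j = rng.choice(len(pos), size=2, replace=False)
            col = matrix.counts[:, pos[i]] + matrix.counts[:, pos[j]]
            new_cols.append(col)
            pa, pb = singlets[i], singlets[j]
            row = truth.loc[pa].to_dict()
            row.update(
                population="doublet", pseudotime=np.nan, tier=-1, phase="low",
                is_doublet=True, parent1=pa, parent2=pb,
                lineage=bool(truth.loc[pa, "lineage"] or truth.loc[pb, "lineage"]),
                library_size=int(truth.loc[pa, "library_size"] + truth.loc[pb, "library_size"]),
                mito_fraction=np.nan,
            )
            new_rows.append(row)
            new_ids.append(f"{animal}_dbl{k:04d}")
    if not new_rows:
        return matrix, truth
    counts = sp.hstack([matrix.counts] + new_cols).tocsr()
    add = pd.DataFrame(new_rows, index=pd.Index(new_ids, name="barcode"))
    truth_out = pd.concat([truth, add[truth.columns]])
    barcodes = truth_out[["animal", "arm"]].copy()
    return CountMatrix(counts, matrix.genes.copy(), barcodes), truth_out


def make_hybrids(
    matrix: CountMatrix,
    truth: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    n: int,
    seed: int,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Append ``n`` hybrid barcodes, each the count-sum of one random cell
    from ``pop_a`` and one from ``pop_b`` (a controlled doublet fixture for
    doublet-cluster detection)."""
    rng = np.random.default_rng(seed)
    a_ids = truth.index[truth["population"] == pop_a]
    b_ids = truth.index[truth["population"] == pop_b]
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError("both parent populations must be present")
    cols, rows, ids = [], [], []
    pos = matrix.barcodes.index
    for k in range(n):
        pa = a_ids[rng.integers(len(a_ids))]
        pb = b_ids[rng.integers(len(b_ids))]
        cols.append(matrix.counts[:, pos.get_loc(pa)] + matrix.counts[:, pos.get_loc(pb)])
        row = truth.loc[pa].to_dict()
        row.update(
            population="doublet", pseudotime=np.nan, tier=-1, phase="low",
            is_doublet=True, parent1=pa, parent2=pb,
            lineage=bool(truth.loc[pa, "lineage"] or truth.loc[pb, "lineage"]),
            library_size=int(truth.loc[pa, "library_size"] + truth.loc[pb, "library_size"]),
            mito_fraction=np.nan,
        )
        rows.append(row)
        ids.append(f"hyb_{k:04d}")
    counts = sp.hstack([matrix.counts] + cols).tocsr()
    add = pd.DataFrame(rows, index=pd.Index(ids, name="barcode"))
    truth_out = pd.concat([truth, add[truth.columns]])
    barcodes = truth_out[["animal", "arm"]].copy()
    return CountMatrix(counts, matrix.genes.copy(), barcodes), truth_out


# ---------------------------------------------------------------------------
# default study-structured configuration
# ---------------------------------------------------------------------------

STROMAL_MARKERS = {
    "astrocyte": ["Gfap", "Aqp4", "Slc1a3"],
    "oligodendrocyte": ["Sox10", "Olig1", "Mbp"],
    "microglia": ["Cx3cr1", "Aif1", "Csf1r"],
    "endothelial": ["Pecam1", "Cldn5", "Flt1"],
    "fibroblast": ["Col1a1", "Dcn", "Lum"],
    "pericyte": ["Pdgfrb", "Rgs5", "Kcnj8"],
}

EARLY_MARKERS = ["Atoh1", "Sfrp1", "Ptch1", "Mycn"]
LATE_MARKERS = ["Rbfox3", "Cntn2", "Grin2b", "Neurod1", "Nhlh1", "Gabra6", "Cntn1"]

MT_GENES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]

N_HOUSEKEEPING = 800
N_PROGRAM_POOL = 400
N_PATHWAY = 100
N_PROGRAM_PER_POP = 100
N_STRONG_PER_POP = 32
N_EARLY_FILL = 126
N_LATE_FILL = 123
N_HUMAN = 150

STRONG_PREFIX = {
    "astrocyte": "AstS", "oligodendrocyte": "OliS", "microglia": "MicS",
    "endothelial": "EndS", "fibroblast": "FibS", "pericyte": "PerS",
}

W_PROGRAM = 3e-4       # moderate shared-pool program genes (doublet signature)
W_STRONG = 1.2e-3      # strong population-defining blocks (drive PCA/clustering)
W_TRAJ = 1.4e-3        # early/late trajectory blocks
W_COUPLING = 8e-4      # regulator/target pair
W_BASELINE = 2e-5      # leaky floor on every mouse gene
HK_MASS = 1.0          # housekeeping lognormal mass before renormalization


def _strong_block(name: str) -> list[str]:
    canonical = STROMAL_MARKERS[name]
    fill = [
        f"{STRONG_PREFIX[name]}{i:02d}"
        for i in range(1, N_STRONG_PER_POP - len(canonical) + 1)
    ]
    return canonical + fill


def default_gene_table() -> pd.DataFrame:
    """Gene universe for the default cohort (mouse + human spike-in genes)."""
    phase_sets = load_cell_cycle_genes()
    cycle_genes = [g for genes in phase_sets.values() for g in genes]
    names = (
        [f"Hk{i:04d}" for i in range(1, N_HOUSEKEEPING + 1)]
        + [f"Prg{i:04d}" for i in range(1, N_PROGRAM_POOL + 1)]
        + [g for name in STROMAL_MARKERS for g in _strong_block(name)]
        + EARLY_MARKERS + [f"Pro{i:03d}" for i in range(1, N_EARLY_FILL + 1)]
        + LATE_MARKERS + [f"Dif{i:03d}" for i in range(1, N_LATE_FILL + 1)]
        + ["Sufu", "Gli1"]
        + [f"Shp{i:04d}" for i in range(1, N_PATHWAY + 1)]
        + cycle_genes
        + MT_GENES
        + ["Yfp"]
        + [f"hg19_HHK{i:04d}" for i in range(1, N_HUMAN + 1)]
    )
    index = pd.Index(names, name="gene")
    species = np.where(index.str.startswith("hg19_"), "human", "mouse")
    mito = index.str.startswith("mt-")
    transgene = index.isin(["Yfp"])
    return pd.DataFrame(
        {"species": species, "mito": mito, "transgene": transgene}, index=index
    )


def default_config(seed: int = 0, structure_seed: int = 7) -> SimulationConfig:
    """Study-structured default cohort: six stromal populations plus one
    three-tier differentiation continuum, five animals per arm, ~300 cells
    per animal, doublets, ambient RNA, mitochondrial stress, human spike-in,
    Yfp lineage reporter, and a treated arm that depletes the continuum,
    shifts it toward the differentiated end and flips the Sufu->Gli1
    coupling sign.

    ``structure_seed`` fixes the (config-level, not simulation-level) random
    assignment of shared-pool program genes to populations.
    """
    genes = default_gene_table()
    G = len(genes)
    gene_index = genes.index
    srng = np.random.default_rng(structure_seed)

    mouse = (genes["species"] == "mouse").to_numpy() & ~genes["mito"].to_numpy(bool)
    hk_idx = gene_index.get_indexer([f"Hk{i:04d}" for i in range(1, N_HOUSEKEEPING + 1)])
    hk_weights = srng.lognormal(0.0, 1.0, size=N_HOUSEKEEPING)
    hk_weights = HK_MASS * hk_weights / hk_weights.sum()
    pool_idx = gene_index.get_indexer([f"Prg{i:04d}" for i in range(1, N_PROGRAM_POOL + 1)])

    # differentiation-stage fill genes are tissue-wide, not tumor-specific:
    # stromal cells carry them at the trajectory-average level so the
    # continuum manifests as a gradient axis rather than an identity axis
    early_fill = gene_index.get_indexer([f"Pro{i:03d}" for i in range(1, N_EARLY_FILL + 1)])
    late_fill = gene_index.get_indexer([f"Dif{i:03d}" for i in range(1, N_LATE_FILL + 1)])

    def base_program() -> np.ndarray:
        p = np.zeros(G)
        p[mouse] = W_BASELINE
        p[hk_idx] = hk_weights
        p[early_fill] += 0.25 * W_TRAJ
        p[late_fill] += 0.20 * W_TRAJ
        return p

    populations = []
    lineage_fractions = {"astrocyte": 0.08, "oligodendrocyte": 0.08}
    for name in STROMAL_MARKERS:
        p = base_program()
        own_pool = srng.choice(pool_idx, size=N_PROGRAM_PER_POP, replace=False)
        p[own_pool] += W_PROGRAM
        p[gene_index.get_indexer(_strong_block(name))] += W_STRONG
        populations.append(
            Population(name, 25, p, lineage_fraction=lineage_fractions.get(name, 0.0))
        )

    early_block = gene_index.get_indexer(
        EARLY_MARKERS + [f"Pro{i:03d}" for i in range(1, N_EARLY_FILL + 1)]
    )
    late_block = gene_index.get_indexer(
        LATE_MARKERS + [f"Dif{i:03d}" for i in range(1, N_LATE_FILL + 1)]
    )
    traj_pool = srng.choice(pool_idx, size=N_PROGRAM_PER_POP, replace=False)
    coup_idx = gene_index.get_indexer(["Sufu", "Gli1"])

    pathway_idx = gene_index.get_indexer(
        [f"Shp{i:04d}" for i in range(1, N_PATHWAY + 1)]
    )

    def traj_base() -> np.ndarray:
        # fill genes enter through the early/late blocks instead of the
        # tissue-wide baseline, so the trajectory mean matches the stroma
        p = base_program()
        p[early_fill] -= 0.25 * W_TRAJ
        p[late_fill] -= 0.20 * W_TRAJ
        p[traj_pool] += W_PROGRAM
        p[pathway_idx] += W_PROGRAM
        p[coup_idx] += W_COUPLING
        return p

    early = traj_base()
    early[early_block] += W_TRAJ
    # canonical markers are the strongest genes of their program
    early[gene_index.get_indexer(EARLY_MARKERS)] += 0.6 * W_TRAJ
    late = traj_base()
    late[late_block] += W_TRAJ
    late[gene_index.get_indexer(LATE_MARKERS)] += 0.6 * W_TRAJ
    trajectory = TrajectoryPopulation(
        "cgnp_tumor", 150, early, late, lineage_fraction=0.8, cycling_fraction=0.7
    )

    human = np.zeros(G)
    h_idx = np.flatnonzero((genes["species"] == "human").to_numpy())
    human[h_idx] = srng.lognormal(0.0, 1.0, size=len(h_idx))

    effects = {
        "vehicle": TreatmentEffect(coupling_sign=1),
        "treated": TreatmentEffect(
            population_multipliers={"cgnp_tumor": 0.45},
            tier_shift=1.2,
            coupling_sign=-1,
        ),
    }

    return SimulationConfig(
        genes=genes,
        populations=populations,
        trajectories=[trajectory],
        effects=effects,
        human_program=human,
        phase_gene_sets=load_cell_cycle_genes(),
        coupling=CouplingSpec(
            "Sufu", "Gli1", strength=0.9,
            module_genes=[f"Shp{i:04d}" for i in range(1, N_PATHWAY + 1)],
        ),
        seed=seed,
    )
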