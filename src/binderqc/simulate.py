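"""Synthetic competition libraries and pooled-screen count simulation.

The generator plants the failure modes observed in crowd-sourced CAR binder
libraries so every downstream stage is testable without external data:

- ``functional_enriched`` — moderately K/E-helical designs with a planted
  CD20-specific proliferation advantage;
- ``neutral`` — low K+E-helix designs with no condition-specific effect;
- ``mpnn_ke_dropout`` — heavily helical, K/E-rich designs (the fixed-backbone
  design-model signature) that drop below the read-recovery threshold;
- ``cys_depleting`` — cysteine-rich designs with a planted CD20-specific
  depletion, emulating disulfide-driven tonic signaling.

Counts follow a log-normal input abundance with negative-binomial replicate
noise (mean mu, variance mu(1+phi*mu)) and an optional jackpot mechanism in
which a clone stochastically expands in one replicate independent of fitness.
All randomness flows from ``SimConfig.seed`` through spawned child streams,
so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from binderqc import io as bqio


class ConfigurationError(ValueError):
    """Raised for invalid class parameters or simulation settings."""


# Background residue frequencies (approximate natural abundances), used for
# non-planted positions. Cysteine is excluded everywhere except the
# cys_depleting class, and K/E are excluded from helix fill so the planted
# K+E-helix ratio is exact.
_BACKGROUND = {
    "A": 0.089, "D": 0.054, "E": 0.062, "F": 0.040, "G": 0.074,
    "H": 0.022, "I": 0.056, "K": 0.058, "L": 0.099, "M": 0.024,
    "N": 0.043, "P": 0.047, "Q": 0.039, "R": 0.051, "S": 0.068,
    "T": 0.056, "V": 0.072, "W": 0.013, "Y": 0.033,
}


def _norm_freqs(exclude: set[str]) -> tuple[list[str], np.ndarray]:
    items = [(aa, w) for aa, w in _BACKGROUND.items() if aa not in exclude]
    aas = [a for a, _ in items]
    w = np.array([x for _, x in items])
    return aas, w / w.sum()


def default_codon_table() -> dict[str, list[tuple[str, float]]]:
    """Uniform weights over synonymous codons of the standard genetic code.

    K and E are encoded by the A-rich codons AAA/AAG and GAA/GAG, so K/E-rich
    proteins reproducibly yield adenosine-dinucleotide-rich DNA.
    """
    table: dict[str, list[tuple[str, float]]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        table.setdefault(aa, []).append(codon)
    return {aa: [(c, 1.0 / len(cs)) for c in sorted(cs)] for aa, cs in table.items()}


@dataclass(frozen=True)
class DesignClass:
    """Ground-truth parameters of one planted design category."""

    name: str
    ke_helix_target: float
    helix_frac_target: float
    cys_count: int = 0
    log2_effect_cd20: float = 0.0
    fitness_log2: float = 0.0
    dropout: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.ke_helix_target <= 1.0):
            raise ConfigurationError(f"{self.name}: ke_helix_target outside [0,1]")
        if not (0.0 <= self.helix_frac_target <= 1.0):
            raise ConfigurationError(f"{self.name}: helix_frac_target outside [0,1]")
        if self.ke_helix_target > self.helix_frac_target:
            raise ConfigurationError(
                f"{self.name}: K+E-helix target exceeds helix fraction target"
            )
        if self.cys_count < 0:
            raise ConfigurationError(f"{self.name}: negative cys_count")
        if self.name == "mpnn_ke_dropout" and not self.dropout:
            raise ConfigurationError("mpnn_ke_dropout class must have dropout=True")
        if self.name == "cys_depleting" and self.log2_effect_cd20 >= 0:
            raise ConfigurationError("cys_depleting class must have log2_effect_cd20 < 0")


def default_classes() -> dict[str, DesignClass]:
    """Study-condition class parameters.

    K+E-helix targets mirror the observed category means (0.35 non-recovered
    fixed-backbone designs, 0.15-0.18 recovered/proliferating, 0.04 designs
    without a significant change); the dropout class is ~83% helical.
    """
    return {
        "functional_enriched": DesignClass(
            "functional_enriched", ke_helix_target=0.18, helix_frac_target=0.75,
            log2_effect_cd20=1.5,
        ),
        "neutral": DesignClass(
            "neutral", ke_helix_target=0.04, helix_frac_target=0.55,
        ),
        "mpnn_ke_dropout": DesignClass(
            "mpnn_ke_dropout", ke_helix_target=0.35, helix_frac_target=0.83,
            dropout=True,
        ),
        "cys_depleting": DesignClass(
            "cys_depleting", ke_helix_target=0.04, helix_frac_target=0.50,
            cys_count=4, log2_effect_cd20=-1.5,
        ),
    }


# Proportions loosely mirroring the screened cohort: ~42% dropout, ~6%
# enriched, a small depleted tail, remainder neutral.
DEFAULT_CLASS_COUNTS = {
    "functional_enriched": 70,
    "neutral": 600,
    "mpnn_ke_dropout": 500,
    "cys_depleting": 30,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic competition + screen.

    The defaults define the simulated study conditions: 80-residue designs,
    three replicates per co-culture condition, 1e6 expected reads per
    replicate, log-normal input abundance (sigma on the natural-log scale)
    and NB dispersion phi = 0.1. Screen depth and dispersion are not reported
    for the real screen, so they are explicit configuration, not constants.
    """

    n_designs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    classes: dict[str, DesignClass] = field(default_factory=default_classes)
    seq_length: int = 80
    codon_table: dict[str, list[tuple[str, float]]] = field(default_factory=default_codon_table)
    input_abundance_sigma: float = 0.7
    nb_dispersion: float = 0.1
    depth_per_replicate: int = 1_000_000
    n_replicates_per_condition: int = 3
    jackpot_prob: float = 0.0
    jackpot_scale: float = 20.0
    target_jitter: float = 0.04      # per-design uniform jitter on class targets
    dropout_log2: float = -10.0      # abundance penalty applied to dropout designs
    n_teams: int = 8
    mpnn_frac_other: float = 0.5     # P(used_mpnn) outside the dropout class
    seed: int = 0

    def validate(self) -> None:
        if self.depth_per_replicate <= 0:
            raise ConfigurationError("depth_per_replicate must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.input_abundance_sigma <= 0:
            raise ConfigurationError("input_abundance_sigma must be > 0")
        if any(n < 0 for n in self.n_designs.values()):
            raise ConfigurationError("negative class count")
        for name in self.n_designs:
            if name not in self.classes:
                raise ConfigurationError(f"unknown design class {name!r}")
            self.classes[name].validate()
        for aa, codons in self.codon_table.items():
            total = sum(w for _, w in codons)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"codon weights for {aa} sum to {total}, not 1")


@dataclass
class DesignRecord:
    """One submitted binder: sequences plus method metadata."""

    design_id: str
    team: str
    protein: str
    dna: str
    design_class: str
    used_mpnn: bool
    ss: str | None = None
    structure_path: str | None = None


def codon_optimize(aa_seq: str, codon_table=None, seed: int | np.random.Generator = 0) -> str:
    """Reverse-translate a protein by sampling codons from a weighted table.

    The output always has length 3x the protein and translates back to the
    input under the standard genetic code.
    """
    table = codon_table or default_codon_table()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for aa in aa_seq:
        if aa not in table:
            raise ConfigurationError(f"no codons for residue {aa!r}")
        codons, weights = zip(*table[aa])
        out.append(codons[rng.choice(len(codons), p=np.asarray(weights))])
    return "".join(out)


def _helix_layout(n_helix: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean helix mask: n_helix residues in 1-3 contiguous blocks."""
    mask = np.zeros(length, dtype=bool)
    if n_helix == 0:
        return mask
    n_blocks = max(1, min(3, n_helix // 14, length - n_helix + 1))
    # split n_helix into n_blocks nearly equal parts
    sizes = [n_helix // n_blocks + (1 if i < n_helix % n_blocks else 0) for i in range(n_blocks)]
    gaps = length - n_helix
    # distribute coil gaps around blocks (n_blocks+1 slots), each interior slot >= 1 when possible
    slots = n_blocks + 1
    gap_sizes = [gaps // slots + (1 if i < gaps % slots else 0) for i in range(slots)]
    order = rng.permutation(slots)
    gap_sizes = [gap_sizes[i] for i in order]
    pos = 0
    for b, size in enumerate(sizes):
        pos += gap_sizes[b]
        mask[pos : pos + size] = True
        pos += size
    return mask


def _generate_one(
    cls: DesignClass, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, str, float, float]:
    """One (protein, ss) pair hitting jittered class targets exactly (to rounding)."""
    L = cfg.seq_length
    w = cfg.target_jitter

    def jitter(target: float, upper: float = 1.0) -> float:
        if target == 0.0:
            return 0.0
        return float(np.clip(target + rng.uniform(-w, w), 0.0, upper))

    helix_t = jitter(cls.helix_frac_target)
    ke_t = jitter(cls.ke_helix_target, upper=helix_t)
    n_helix = round(helix_t * L)
    n_ke = min(round(ke_t * L), n_helix)

    mask = _helix_layout(n_helix, L, rng)
    helix_pos = np.flatnonzero(mask)
    coil_pos = np.flatnonzero(~mask)

    seq = np.empty(L, dtype="<U1")
    ke_pos = rng.choice(helix_pos, size=n_ke, replace=False) if n_ke else np.array([], dtype=int)
    seq[ke_pos] = rng.choice(["K", "E"], size=n_ke)
    fill_helix = np.setdiff1d(helix_pos, ke_pos)
    aas_h, p_h = _norm_freqs({"C", "K", "E"})
    seq[fill_helix] = rng.choice(aas_h, size=len(fill_helix), p=p_h)
    aas_c, p_c = _norm_freqs({"C"})
    seq[coil_pos] = rng.choice(aas_c, size=len(coil_pos), p=p_c)

    if cls.cys_count:
        pool = coil_pos if len(coil_pos) >= cls.cys_count else np.setdiff1d(np.arange(L), ke_pos)
        cys_at = rng.choice(pool, size=cls.cys_count, replace=False)
        seq[cys_at] = "C"

    ss = "".join("H" if m else "C" for m in mask)
    return "".join(seq), ss, helix_t, ke_t


def generate_designs(config: SimConfig):
    """Generate the design library.

    Returns ``(designs, truth)``: a list of :class:`DesignRecord` and a
    pandas DataFrame of per-design ground truth (class, planted effects,
    realized targets), indexed by design_id. Deterministic given
    ``config.seed``.
    """
    import pandas as pd

    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_seq, rng_dna = [np.random.default_rng(s) for s in root.spawn(2)]

    designs: list[DesignRecord] = []
    truth_rows = []
    idx = 0
    for cls_name in sorted(config.n_designs):
        cls = config.classes[cls_name]
        for _ in range(config.n_designs[cls_name]):
            protein, ss, helix_t, ke_t = _generate_one(cls, config, rng_seq)
            dna = codon_optimize(protein, config.codon_table, rng_dna)
            design_id = f"d{idx:05d}"
            team = f"team_{idx % config.n_teams + 1:02d}"
            used_mpnn = cls.dropout or bool(rng_seq.random() < config.mpnn_frac_other)
            designs.append(
                DesignRecord(design_id, team, protein, dna, cls_name, used_mpnn, ss=ss)
            )
            truth_rows.append(
                {
                    "design_id": design_id,
                    "design_class": cls_name,
                    "log2_effect_cd20": cls.log2_effect_cd20,
                    "fitness_log2": cls.fitness_log2,
                    "dropout": cls.dropout,
                    "helix_target": helix_t,
                    "ke_helix_target": ke_t,
                }
            )
            idx += 1
    truth_cols = [
        "design_id", "design_class", "log2_effect_cd20", "fitness_log2",
        "dropout", "helix_target", "ke_helix_target",
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_cols).set_index("design_id")
    return designs, truth


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, var mu(1+phi*mu)) via gamma-Poisson mixing."""
    mean = np.clip(mean, 1e-12, None)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean) if phi > 0 else mean
    return rng.poisson(lam)


def simulate_screen(designs: list[DesignRecord], config: SimConfig):
    """Simulate the pooled proliferation screen for a design library.

    Produces a :class:`binderqc.screen.CountMatrix` with an ``input`` column
    and three replicates per co-culture condition. Per replicate, design i's
    expected count is ``depth * p_i`` where p is the condition-specific
    relative abundance: input abundance x 2^(fitness) x 2^(effect) in the
    CD20+ condition, with dropout designs additionally penalized by
    ``2^dropout_log2``. Relative abundances are renormalized per condition
    (sequencing depth is fixed), so strong planted effects incur the usual
    small compositional bias in fold-change estimates.
    """
    from binderqc.screen import CountMatrix

    if not designs:
        raise ConfigurationError("no designs to screen")
    config.validate()
    root = np.random.SeedSequence((config.seed, 1))
    rng = np.random.default_rng(root)

    n = len(designs)
    cls = [config.classes[d.design_class] for d in designs]
    base = np.exp(rng.normal(0.0, config.input_abundance_sigma, size=n))
    effect = np.array([c.log2_effect_cd20 for c in cls])
    fitness = np.array([c.fitness_log2 for c in cls])
    drop = np.array([c.dropout for c in cls])

    post = base * np.exp2(fitness + np.where(drop, config.dropout_log2, 0.0))
    abund = {
        "input": base / base.sum(),
        "cd20neg": post / post.sum(),
        "cd20pos": (post * np.exp2(effect)) / (post * np.exp2(effect)).sum(),
    }

    depth = config.depth_per_replicate
    phi = config.nb_dispersion
    cols: dict[str, np.ndarray] = {}
    cols["input"] = _nb_sample(rng, depth * abund["input"], phi)
    for cond in ("cd20pos", "cd20neg"):
        for r in range(1, config.n_replicates_per_condition + 1):
            mu = depth * abund[cond]
            if config.jackpot_prob > 0:
                hit = rng.random(n) < config.jackpot_prob
                mu = np.where(hit, mu * config.jackpot_scale, mu)
            cols[f"{cond}_{r}"] = _nb_sample(rng, mu, phi)

    import pandas as pd

    counts = pd.DataFrame(cols, index=[d.design_id for d in designs])
    counts.index.name = "design_id"
    return CountMatrix.from_frame(counts)


def write_fixture(designs: list[DesignRecord], counts, outdir: str | Path) -> dict[str, Path]:
    """Write a complete plain-text fixture: protein/DNA FASTA, metadata TSV,
    counts TSV and SS TSV, all re-readable via :mod:`binderqc.io`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_fasta": outdir / "protein.fasta",
        "dna_fasta": outdir / "dna.fasta",
        "metadata": outdir / "metadata.tsv",
        "counts": outdir / "counts.tsv",
        "ss": outdir / "ss.tsv",
    }
    bqio.write_fasta({d.design_id: d.protein for d in designs}, paths["protein_fasta"])
    bqio.write_fasta({d.design_id: d.dna for d in designs}, paths["dna_fasta"])
    bqio.write_metadata(designs, paths["metadata"])
    if counts is not None:
        bqio.write_counts(counts, paths["counts"])
    bqio.write_ss({d.design_id: d.ss for d in designs if d.ss}, paths["ss"])
    return paths
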