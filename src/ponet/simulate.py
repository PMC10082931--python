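"""Synthetic paired total/polysomal time courses with planted structure.

The generator emulates a two-fraction microarray design over an ordered
developmental time course (by default 4 maturation + 5 germination stages,
3 replicates): per-gene log2 baselines follow a random walk over stages,
polysomal signal adds a planted PO component, and everything sits on a
log2 scale with a noise floor near 4. Planted structure — step-like PO
shifts at one transition, lagged regulator->target dependencies, shared
module trajectories, and below-noise genes — exercises every downstream
stage, and the emitted truth record is the recovery oracle.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import DEFAULT_STAGES, ExpressionMatrix, POLYSOMAL, TOTAL, _sample_columns

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"


@dataclass
class SimConfig:
    """Parameters of the synthetic study design (defaults = study conditions)."""

    n_genes: int = 1000
    stages: tuple = DEFAULT_STAGES
    n_replicates: int = 3
    noise_sd: float = 0.2           # log2-scale replicate noise
    # planted differential-PO shifts at stages[de_transition-1] -> stages[de_transition]
    n_de_up: int = 200
    n_de_down: int = 100
    de_transition: int = 1
    de_effect_mean: float = 1.5
    de_effect_sd: float = 0.25
    # planted directed cascades (lagged linear dependence on the regulator PO)
    n_regulators: int = 10
    targets_per_regulator: int = 3
    reg_lag: int = 1
    reg_effect: float = 0.8
    reg_signal_sd: float = 1.5      # sd of the regulator's PO trajectory (log2)
    reg_smooth: int = 3             # moving-average window of the trajectory
    target_noise_sd: float = 0.1
    # planted co-trajectory modules
    n_modules: int = 3
    module_size: int = 20
    module_amplitude: float = 1.0
    # background dynamics
    walk_sd: float = 0.3
    baseline_lo: float = 5.0
    baseline_hi: float = 11.0
    noise_floor_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_genes=self.n_genes, n_replicates=self.n_replicates, n_de_up=self.n_de_up,
            n_de_down=self.n_de_down, n_regulators=self.n_regulators,
            targets_per_regulator=self.targets_per_regulator,
            n_modules=self.n_modules, module_size=self.module_size,
        )
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if len(self.stages) < 2:
            raise ConfigError("need at least 2 stages")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not (1 <= self.de_transition < len(self.stages)):
            raise ConfigError("de_transition must index a stage transition")
        if self.reg_lag < 1:
            raise ConfigError("regulator lag must be >= 1 stage")
        planted = (
            self.n_de_up + self.n_de_down
            + self.n_regulators * (1 + self.targets_per_regulator)
            + self.n_modules * self.module_size
        )
        if planted > self.n_genes:
            raise ConfigError(
                f"infeasible config: {planted} planted genes exceed n_genes={self.n_genes}"
            )


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    de_genes: dict = field(default_factory=dict)     # gene -> (transition, signed effect)
    edges: list = field(default_factory=list)        # (regulator, target, lag, coefficient)
    modules: dict = field(default_factory=dict)      # gene -> module id
    motif_genes: dict = field(default_factory=dict)  # gene -> [(region, offset), ...]
    noise_floor_genes: list = field(default_factory=list)

    @property
    def signal_genes(self) -> set:
        """Every gene carrying any planted PO signal (DE, module or cascade)."""
        return (
            set(self.de_genes)
            | set(self.modules)
            | {g for e in self.edges for g in e[:2]}
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["de_genes"] = {g: tuple(v) for g, v in d["de_genes"].items()}
        d["edges"] = [tuple(e) for e in d["edges"]]
        d["motif_genes"] = {g: [tuple(p) for p in v] for g, v in d["motif_genes"].items()}
        return cls(**d)


def _gene_names(n: int):
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_dataset(config: SimConfig):
    """Generate (total, polysomal, truth) under ``config``.

    Total signal per gene is a random walk over stages plus replicate noise;
    polysomal signal adds the planted PO component: a signed step at the
    designated transition for differential genes, a shared scaled template
    for module genes, and a lagged linear function of the regulator's PO for
    cascade targets. A configurable fraction of background genes is placed
    entirely below the noise floor.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_stages, n_rep = config.n_genes, len(config.stages), config.n_replicates
    genes = _gene_names(n)
    truth = SyntheticTruth()

    # --- assign roles over disjoint gene blocks
    cursor = 0

    def take(k):
        nonlocal cursor
        block = genes[cursor:cursor + k]
        cursor += k
        return block

    de_up = take(config.n_de_up)
    de_down = take(config.n_de_down)
    regulators = take(config.n_regulators)
    targets = [take(config.targets_per_regulator) for _ in regulators]
    module_genes = [take(config.module_size) for _ in range(config.n_modules)]
    background = genes[cursor:]
    n_floor = int(round(config.noise_floor_fraction * n))
    floor_genes = background[:n_floor] if n_floor <= len(background) else background
    truth.noise_floor_genes = list(floor_genes)

    # --- stage-level baselines (random walk, log2 scale)
    start = rng.uniform(config.baseline_lo, config.baseline_hi, size=n)
    steps = rng.normal(0.0, config.walk_sd, size=(n, n_stages - 1))
    baseline = np.hstack([start[:, None], start[:, None] + np.cumsum(steps, axis=1)])

    # --- planted PO signal per gene x stage
    po_signal = np.zeros((n, n_stages))
    gi = {g: i for i, g in enumerate(genes)}
    transition = f"{config.stages[config.de_transition - 1]}:{config.stages[config.de_transition]}"
    for g in de_up:
        eff = rng.normal(config.de_effect_mean, config.de_effect_sd)
        po_signal[gi[g], config.de_transition:] = eff
        truth.de_genes[g] = (transition, float(eff))
    for g in de_down:
        eff = rng.normal(config.de_effect_mean, config.de_effect_sd)
        po_signal[gi[g], config.de_transition:] = -eff
        truth.de_genes[g] = (transition, float(-eff))
    for m, block in enumerate(module_genes, start=1):
        template = np.cumsum(rng.normal(0.0, 1.0, size=n_stages))
        template -= template.mean()
        template *= config.module_amplitude / max(template.std(), 1e-9)
        for g in block:
            po_signal[gi[g]] = template + rng.normal(0.0, 0.1, size=n_stages)
            truth.modules[g] = m
    for r, block in zip(regulators, targets):
        # smooth developmental trajectory: low-pass-filtered random walk, so
        # the 1-stage-lagged dependence below remains visible (and orientable)
        # to scorers that see contemporaneous samples
        raw = np.cumsum(rng.normal(0.0, 1.0, size=n_stages + max(config.reg_smooth - 1, 0)))
        if config.reg_smooth > 1:
            kernel = np.ones(config.reg_smooth) / config.reg_smooth
            walk = np.convolve(raw, kernel, mode="valid")[:n_stages]
        else:
            walk = raw[:n_stages]
        walk -= walk.mean()
        walk *= config.reg_signal_sd / max(walk.std(), 1e-9)
        po_signal[gi[r]] = walk
        for t in block:
            lagged = np.zeros(n_stages)
            lagged[config.reg_lag:] = walk[:-config.reg_lag or None][: n_stages - config.reg_lag]
            po_signal[gi[t]] = config.reg_effect * lagged + rng.normal(
                0.0, config.target_noise_sd, size=n_stages
            )
            truth.edges.append((r, t, config.reg_lag, config.reg_effect))

    # --- expand to replicates with noise
    t_vals = np.repeat(baseline, n_rep, axis=1) + rng.normal(
        0.0, config.noise_sd, size=(n, n_stages * n_rep)
    )
    p_vals = np.repeat(baseline + po_signal, n_rep, axis=1) + rng.normal(
        0.0, config.noise_sd, size=(n, n_stages * n_rep)
    )

    # --- noise-floor genes: everything strictly below the threshold
    if floor_genes:
        idx = [gi[g] for g in floor_genes]
        t_vals[idx] = rng.uniform(2.0, 3.8, size=(len(idx), n_stages * n_rep))
        p_vals[idx] = rng.uniform(2.0, 3.8, size=(len(idx), n_stages * n_rep))

    cols_t = _sample_columns(config.stages, TOTAL, n_rep)
    cols_p = _sample_columns(config.stages, POLYSOMAL, n_rep)
    total = ExpressionMatrix(pd.DataFrame(t_vals, index=genes, columns=cols_t), config.stages)
    polysomal = ExpressionMatrix(pd.DataFrame(p_vals, index=genes, columns=cols_p), config.stages)
    return total, polysomal, truth


# ---------------------------------------------------------------------------
# transcript sequences
# ---------------------------------------------------------------------------

@dataclass
class TranscriptConfig:
    """Layout and composition of synthetic transcripts."""

    utr5_len: int = 150
    cds_len: int = 450              # nucleotides, multiple of 3, includes stop codon
    utr3_len: int = 200
    composition: tuple = (0.3, 0.2, 0.2, 0.3)   # A, C, G, T background
    pi_mod: float = 0.6             # motif-insert probability in the motif module
    pi_bg: float = 0.05             # motif-insert probability elsewhere
    motif_module: int = 1           # module id whose genes carry the motif
    gc_shift: float = 0.0           # CDS GC shift for the designated set
    gc_shift_genes: tuple = ()
    seed: int = 0

    def validate(self):
        if self.cds_len % 3 != 0:
            raise ConfigError(f"cds_len must be a multiple of 3, got {self.cds_len}")
        if self.cds_len < 6:
            raise ConfigError("cds_len must allow a start and a stop codon")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ConfigError("background composition must sum to 1")


def _sample_codons(rng, n_codons, composition):
    """Sense codons drawn from the 0-order composition, renormalised without stops."""
    codons = [a + b + c for a in BASES for b in BASES for c in BASES]
    comp = dict(zip(BASES, composition))
    probs = np.array(
        [comp[x[0]] * comp[x[1]] * comp[x[2]] if x not in STOP_CODONS else 0.0 for x in codons]
    )
    probs /= probs.sum()
    picks = rng.choice(len(codons), size=n_codons, p=probs)
    return "".join(codons[i] for i in picks)


def _shift_composition(composition, gc_shift):
    a, c, g, t = composition
    gc = c + g
    new_gc = min(max(gc + gc_shift, 1e-6), 1 - 1e-6)
    scale_gc = new_gc / gc
    scale_at = (1 - new_gc) / (1 - gc)
    return (a * scale_at, c * scale_gc, g * scale_gc, t * scale_at)


def simulate_transcript_set(truth: SyntheticTruth, pwm, genes, config: TranscriptConfig):
    """Generate transcripts (UTR5+CDS+UTR3) with planted 5'UTR motif placements.

    Genes of the designated motif module receive a PWM-sampled insert with
    probability ``pi_mod``; all other genes with probability ``pi_bg``.
    Placements are recorded in ``truth.motif_genes``. A designated gene set
    gets its CDS composition shifted by ``gc_shift`` in GC fraction. Every CDS
    starts with ATG, ends with a stop codon and contains no internal stop.
    """
    from .features import TranscriptRecord  # local import avoids a cycle

    config.validate()
    if pwm is not None and pwm.width > config.utr5_len:
        raise ConfigError("PWM wider than the 5'UTR to be generated")
    rng = np.random.default_rng(config.seed)
    comp = np.asarray(config.composition)
    shift_set = set(config.gc_shift_genes)
    module_set = {g for g, m in truth.modules.items() if m == config.motif_module}
    records = []
    for gene in genes:
        utr5 = "".join(rng.choice(list(BASES), size=config.utr5_len, p=comp))
        cds_comp = (
            _shift_composition(config.composition, config.gc_shift)
            if gene in shift_set else config.composition
        )
        n_inner = config.cds_len // 3 - 2
        cds = "ATG" + _sample_codons(rng, n_inner, cds_comp) + str(rng.choice(STOP_CODONS))
        utr3 = "".join(rng.choice(list(BASES), size=config.utr3_len, p=comp))
        if pwm is not None:
            pi = config.pi_mod if gene in module_set else config.pi_bg
            if rng.random() < pi:
                insert = pwm.sample(rng)
                offset = int(rng.integers(0, config.utr5_len - pwm.width + 1))
                utr5 = utr5[:offset] + insert + utr5[offset + pwm.width:]
                truth.motif_genes.setdefault(gene, []).append(("UTR5", offset))
        seq = utr5 + cds + utr3
        records.append(
            TranscriptRecord(
                gene=gene,
                sequence=seq,
                utr5=(0, config.utr5_len),
                cds=(config.utr5_len, config.utr5_len + config.cds_len),
                utr3=(config.utr5_len + config.cds_len, len(seq)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# structure tracks
# ---------------------------------------------------------------------------

def simulate_structure_tracks(
    transcripts,
    elevated_genes=(),
    mu_bg: float = 0.35,
    sigma: float = 0.1,
    delta: float = 0.3,
    seed: int = 0,
):
    """Per-nucleotide structure scores ~ Normal(mu_bg, sigma) clipped to [0, 1];
    genes in ``elevated_genes`` get ``delta`` added over their CDS."""
    rng = np.random.default_rng(seed)
    elevated = set(elevated_genes)
    tracks = {}
    clipped_any = False
    for tr in transcripts:
        scores = rng.normal(mu_bg, sigma, size=len(tr.sequence))
        if tr.gene in elevated:
            s, e = tr.cds
            scores[s:e] += delta
        if np.any(scores < 0) or np.any(scores > 1):
            clipped_any = True
        tracks[tr.gene] = np.clip(scores, 0.0, 1.0)
    if clipped_any and delta != 0:
        log.warning("structure scores clipped to [0, 1] after applying delta=%s", delta)
    return tracks
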