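"""Seeded generator of labelled cytosine-centred windows.

Emulates the study design: positive windows carry a planted
position-weight-matrix (PWM) motif of tunable strength in the flank of
the central cytosine; negative windows are background-composition
sequences.  Both classes have a central 'C', mirroring real benchmark
construction where negatives are centred cytosines not detected as
methylated, so the centre base itself carries no signal.

The PWM gives the consensus base probability 0.25 + 0.75 * effect at
each motif position (other bases uniform): effect 0 makes the classes
identical, effect 1 plants a deterministic consensus.  The motif's
KL divergence from background is therefore a closed-form, monotone
function of ``effect`` (:func:`motif_kl`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .samples import DnaSample, write_samples

BASES = "ACGT"


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int = 500
    n_neg: int = 500
    L: int = 41
    effect: float = 0.6
    motif_width: int = 6
    motif_offset: int = 1  # start offset of the motif, relative to the centre
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    # modqv values emulate an already quality-screened dataset, so the
    # default quality filter (threshold 30, drop_above) leaves them intact
    modqv_range: tuple[float, float] = (0.0, 30.0)

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")
        if self.L < 1 or self.L % 2 == 0:
            raise ValueError("window length must be a positive odd integer")
        if not 0 <= self.effect <= 1:
            raise ValueError("effect must be in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        if any(p < 0 for p in self.background):
            raise ValueError("background probabilities must be non-negative")
        centre = self.L // 2  # 0-based
        start = centre + self.motif_offset
        if self.motif_width < 1:
            raise ValueError("motif_width must be >= 1")
        if start < 0 or start + self.motif_width > self.L:
            raise ValueError(
                f"motif window [{start}, {start + self.motif_width}) overflows "
                f"the {self.L}-bp sequence"
            )
        if self.modqv_range[0] < 0 or self.modqv_range[1] < self.modqv_range[0]:
            raise ValueError("modqv_range must be a non-negative interval")

    @property
    def centre(self) -> int:
        return self.L // 2

    @property
    def motif_start(self) -> int:
        return self.centre + self.motif_offset


def motif_pwm(config: GeneratorConfig) -> tuple[str, np.ndarray]:
    """The consensus string and (width, 4) PWM used for positives."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    consensus_idx = rng.integers(0, 4, size=config.motif_width)
    p_hit = 0.25 + 0.75 * config.effect
    pwm = np.full((config.motif_width, 4), (1.0 - p_hit) / 3.0)
    pwm[np.arange(config.motif_width), consensus_idx] = p_hit
    consensus = "".join(BASES[i] for i in consensus_idx)
    return consensus, pwm


def motif_kl(config: GeneratorConfig) -> float:
    """Closed-form KL divergence of the planted PWM from background,
    summed over motif positions; monotone in ``effect``."""
    _, pwm = motif_pwm(config)
    bg = np.asarray(config.background)
    total = 0.0
    for row in pwm:
        for p, q in zip(row, bg):
            if p > 0 and q > 0:
                total += p * math.log(p / q)
    return total


def generate(config: GeneratorConfig) -> list[DnaSample]:
    """Generate ``n_pos`` positive and ``n_neg`` negative windows.

    Deterministic for a fixed config (including seed).  Positives come
    first, then negatives; all windows have a central 'C' and a
    synthetic modqv score.
    """
    rng = np.random.default_rng(config.seed)
    _, pwm = motif_pwm(config)
    bg = np.asarray(config.background)
    n = config.n_pos + config.n_neg
    seqs = rng.choice(4, size=(n, config.L), p=bg)
    # plant the motif in the positive class
    for j in range(config.motif_width):
        seqs[: config.n_pos, config.motif_start + j] = rng.choice(
            4, size=config.n_pos, p=pwm[j]
        )
    seqs[:, config.centre] = 1  # force central 'C' in both classes
    lo, hi = config.modqv_range
    modqvs = rng.uniform(lo, hi, size=n)
    samples = []
    for i in range(n):
        label = 1 if i < config.n_pos else 0
        tag = "pos" if label else "neg"
        samples.append(DnaSample(
            id=f"synth_{tag}_{i if label else i - config.n_pos}",
            sequence="".join(BASES[b] for b in seqs[i]),
            label=label,
            modqv=float(round(modqvs[i], 3)),
        ))
    return samples


def write_benchmark(samples: Sequence[DnaSample], out_dir) -> dict[str, Path]:
    """Write FASTA + labels TSV + modqv metadata TSV readable by
    :func:`mc4deep.samples.read_samples`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "labels": out / "labels.tsv",
        "metadata": out / "metadata.tsv",
    }
    write_samples(list(samples), paths["fasta"], paths["labels"], paths["metadata"])
    return paths
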