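"""Seeded simulator of motif-embedded multi-label DNA datasets.

Each class is a position weight matrix (PWM); each simulated sequence draws a
Bernoulli label per class and, for every positive label, writes one or more
motif samples from that class's PWM at uniform-random non-overlapping
positions over a random background.  Labels therefore record embeddings
exactly, which keeps them usable as oracle ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import ALPHABET, Dataset, DnaSequence, one_hot_encode

__all__ = [
    "Pwm",
    "SimConfig",
    "make_default_pwms",
    "simulate_dataset",
    "simulate_to_dataset",
]

_MAX_PWM_RETRIES = 1000
_MAX_PLACEMENT_RETRIES = 200


@dataclasses.dataclass(frozen=True)
class Pwm:
    """A named motif: per-position base probabilities over (A, C, G, T)."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"probs must be m x 4, got shape {p.shape}")
        if p.shape[0] < 4:
            raise ValueError(f"motif length must be >= 4, got {p.shape[0]}")
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must be a probability vector")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Mean per-position information content in bits (2 - entropy)."""
        p = np.clip(self.probs, 1e-12, 1.0)
        entropy = -(p * np.log2(p)).sum(axis=1)
        return float((2.0 - entropy).mean())

    def sample(self, rng: np.random.Generator) -> str:
        cum = self.probs.cumsum(axis=1)
        draws = rng.random(len(self))
        idx = (draws[:, None] > cum).sum(axis=1)
        return "".join(ALPHABET[j] for j in idx)


def make_default_pwms(
    c: int,
    m: int = 8,
    sharpness: float = 6.0,
    seed: int = 0,
) -> list[Pwm]:
    """C distinct PWMs with pairwise consensus Hamming distance >= m/2.

    Each row puts probability ``exp(sharpness) / (exp(sharpness) + 3)`` on
    the consensus base, so rows approach one-hot as sharpness grows and the
    information content is monotone in sharpness.
    """
    if c < 1:
        raise ValueError("need C >= 1 classes")
    if m < 4:
        raise ValueError("motif length must be >= 4")
    rng = np.random.default_rng(seed)
    min_dist = m / 2
    consensi: list[np.ndarray] = []
    for ci in range(c):
        for _ in range(_MAX_PWM_RETRIES):
            cand = rng.integers(0, 4, size=m)
            if all((cand != prev).sum() >= min_dist for prev in consensi):
                consensi.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw motif {ci} with pairwise Hamming distance >= "
                f"{min_dist} after {_MAX_PWM_RETRIES} tries; reduce C or increase m"
            )
    p_hit = np.exp(sharpness) / (np.exp(sharpness) + 3.0)
    p_miss = (1.0 - p_hit) / 3.0
    pwms = []
    for ci, cons in enumerate(consensi):
        probs = np.full((m, 4), p_miss)
        probs[np.arange(m), cons] = p_hit
        pwms.append(Pwm(name=f"TF{ci}", probs=probs))
    return pwms


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; ``seed`` is mandatory for reproducibility."""

    n: int
    length: int
    pwms: tuple[Pwm, ...]
    prevalence: float = 0.3
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    embed_per_positive: int = 1
    reverse_complement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pwms", tuple(self.pwms))
        object.__setattr__(self, "background", tuple(self.background))
        if self.n < 1:
            raise ValueError("need n >= 1 sequences")
        if not self.pwms:
            raise ValueError("need at least one class PWM")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.length < max(len(p) for p in self.pwms):
            raise ValueError("sequence length must be >= the longest motif")
        bg = np.asarray(self.background, dtype=np.float64)
        if bg.shape != (4,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a length-4 probability vector")
        if self.embed_per_positive < 1:
            raise ValueError("embed_per_positive must be >= 1")

    @property
    def n_classes(self) -> int:
        return len(self.pwms)

    @property
    def class_names(self) -> list[str]:
        return [p.name for p in self.pwms]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _place_motifs(
    bases: list[str],
    motifs: list[str],
    occupied: list[tuple[int, int]],
    length: int,
    rng: np.random.Generator,
) -> None:
    for motif in motifs:
        m = len(motif)
        for _ in range(_MAX_PLACEMENT_RETRIES):
            start = int(rng.integers(0, length - m + 1))
            if all(start + m <= a or start >= b for a, b in occupied):
                bases[start:start + m] = list(motif)
                occupied.append((start, start + m))
                break
        else:
            raise RuntimeError(
                "could not place a motif without overlap; "
                "increase the sequence length or lower prevalence"
            )


def simulate_dataset(cfg: SimConfig) -> tuple[list[DnaSequence], np.ndarray]:
    """Generate sequences and the exactly-consistent n x C label matrix."""
    rng = np.random.default_rng(cfg.seed)
    bg = np.asarray(cfg.background)
    labels = (rng.random((cfg.n, cfg.n_classes)) < cfg.prevalence).astype(np.uint8)
    sequences = []
    for si in range(cfg.n):
        idx = rng.choice(4, size=cfg.length, p=bg)
        bases = [ALPHABET[j] for j in idx]
        occupied: list[tuple[int, int]] = []
        for ci in range(cfg.n_classes):
            if not labels[si, ci]:
                continue
            motifs = []
            for _ in range(cfg.embed_per_positive):
                motif = cfg.pwms[ci].sample(rng)
                if cfg.reverse_complement and rng.random() < 0.5:
                    motif = motif.translate(_COMPLEMENT)[::-1]
                motifs.append(motif)
            _place_motifs(bases, motifs, occupied, cfg.length, rng)
        sequences.append(DnaSequence(id=f"seq{si}", bases="".join(bases)))
    return sequences, labels


def simulate_to_dataset(cfg: SimConfig) -> Dataset:
    """Simulate and one-hot encode into a :class:`~deepcac.data_io.Dataset`."""
    sequences, labels = simulate_dataset(cfg)
    x = np.stack([one_hot_encode(s) for s in sequences])
    return Dataset(
        x=x,
        y=labels,
        class_names=cfg.class_names,
        ids=[s.id for s in sequences],
    )
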