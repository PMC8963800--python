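"""Labeled protein-pair datasets and the synthetic benchmark generator.

Pairs are featurized by concatenating the two partners' 256-bin texture
histograms into a 512-vector (order as given). Negative pairs can be sampled
under a compartment constraint: when subcellular-localization labels are
supplied, a presumed non-interacting pair must join proteins annotated to
different compartments.

Note on leakage: pairs are split into folds at the pair level, so the same
protein may occur in both training and test pairs. This mirrors the
evaluation protocol being reproduced and is deliberate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ppitex.loop import LoopDescriptor, loop_histogram
from ppitex.pssm import (
    AA_ORDER,
    PSSM,
    ProteinSequence,
    default_base_profile,
    pseudo_pssm,
    write_fasta,
    write_psiblast_pssm,
)

PAIR_DIM = 512
# Motif geometry for the synthetic generator. The patch must out-contrast the
# substitution-matrix background (entries spanning roughly -4..11) for its
# texture codes to replicate across proteins, hence the wide window and the
# large default amplitude.
_MOTIF_WIDTH = 41
_MOTIF_SMOOTH_SIGMA = 0.7


@dataclass(frozen=True)
class ProteinPair:
    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-pair {self.id_a!r} is not allowed")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def key(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


def pair_features(desc_a: LoopDescriptor, desc_b: LoopDescriptor) -> np.ndarray:
    """Concatenate two 256-bin descriptors into one 512-vector [a || b]."""
    if desc_a.histogram.shape != (256,) or desc_b.histogram.shape != (256,):
        raise ValueError("descriptors must be 256-dimensional")
    return np.concatenate([desc_a.histogram, desc_b.histogram])


@dataclass
class InteractionDataset:
    """Pairs, per-protein descriptors and the assembled (X, Y) matrices."""

    pairs: list[ProteinPair]
    descriptors: dict[str, LoopDescriptor]
    X: np.ndarray = field(init=False)
    Y: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        missing = sorted(
            {p for pair in self.pairs for p in (pair.id_a, pair.id_b)}
            - set(self.descriptors)
        )
        if missing:
            raise KeyError(f"pairs reference proteins without descriptors: {missing}")
        self.X = np.array(
            [
                pair_features(self.descriptors[p.id_a], self.descriptors[p.id_b])
                for p in self.pairs
            ]
        ).reshape(len(self.pairs), PAIR_DIM)
        self.Y = np.array([p.label for p in self.pairs], dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class FoldSplit:
    folds: list[np.ndarray]

    def __post_init__(self) -> None:
        concat = np.concatenate(self.folds)
        n = len(concat)
        if len(np.unique(concat)) != n or sorted(concat) != list(range(n)):
            raise ValueError("folds must be disjoint and cover all indices")


def kfold_split(N: int, k: int, seed: int) -> FoldSplit:
    """Seeded random permutation of 0..N-1 cut into k nearly equal folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if N < k:
        raise ValueError(f"cannot split N={N} samples into k={k} folds")
    perm = np.random.default_rng(seed).permutation(N)
    return FoldSplit(folds=np.array_split(perm, k))


def stratified_kfold_split(y: Sequence[int], k: int, seed: int) -> FoldSplit:
    """Class-balanced variant of :func:`kfold_split` (off by default)."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for j, chunk in enumerate(np.array_split(idx, k)):
            folds[j].extend(chunk)
    return FoldSplit(folds=[np.array(sorted(f), dtype=int) for f in folds])


def sample_negative_pairs(
    proteins: Sequence[str],
    positives: Iterable,
    n_neg: int,
    compartments: Mapping[str, str] | None = None,
    seed: int = 0,
) -> list[ProteinPair]:
    """Draw ``n_neg`` distinct presumed-non-interacting pairs.

    Eligible pairs are unordered, not self-pairs, absent from ``positives``,
    and - when ``compartments`` is given - join proteins with different
    compartment labels. Raises if fewer eligible pairs exist than requested,
    stating the maximum.
    """
    pos_keys = {frozenset(p) for p in positives}
    eligible = []
    for a, b in itertools.combinations(proteins, 2):
        if frozenset((a, b)) in pos_keys:
            continue
        if compartments is not None and compartments.get(a) == compartments.get(b):
            continue
        eligible.append((a, b))
    if n_neg > len(eligible):
        raise ValueError(
            f"requested {n_neg} negative pairs but only {len(eligible)} are eligible"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_neg, replace=False)
    return [ProteinPair(*eligible[i], label=0) for i in chosen]


# ---------------------------------------------------------------------------
# Synthetic PPI benchmark
# ---------------------------------------------------------------------------

class SyntheticPPI(NamedTuple):
    sequences: list[ProteinSequence]
    pssms: dict[str, PSSM]
    pairs: list[ProteinPair]


def _smooth_patch(rng: np.random.Generator, amplitude: float, width: int) -> np.ndarray:
    """Random smooth 20 x width additive patch scaled to sd = amplitude."""
    raw = gaussian_filter(rng.standard_normal((20, width)), sigma=_MOTIF_SMOOTH_SIGMA)
    sd = raw.std()
    if sd == 0 or amplitude == 0:
        return np.zeros((20, width))
    return raw * (amplitude / sd)


def _insert(pssm: PSSM, patch: np.ndarray, rng: np.random.Generator) -> None:
    w = patch.shape[1]
    offset = int(rng.integers(0, pssm.length - w + 1))
    pssm.scores[:, offset : offset + w] += patch


def gen_synthetic_ppi(
    n_prot: int,
    n_pos: int,
    n_neg: int,
    seq_len_range: tuple[int, int] = (60, 100),
    signal_strength: float = 60.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticPPI:
    """Generate a fully synthetic, texture-separable PPI dataset.

    Random sequences get pseudo-PSSM profiles. One smooth 20x41 motif patch
    (sd ``signal_strength``) is shared by all interacting pairs and added to
    both partners' profiles at random column offsets, so positives carry a
    common local texture; each partner of a non-interacting pair receives an
    independent random patch of the same amplitude instead. With
    ``signal_strength = 0`` the two classes are statistically identical.

    Pairs are disjoint in their proteins while the pool lasts (each protein
    then receives exactly one patch); once the pool is exhausted, additional
    distinct pairs reuse proteins, which stacks patches and weakens the
    class signal.
    """
    if n_prot < 4:
        raise ValueError("n_prot must be at least 4")
    lo, hi = seq_len_range
    if lo < 50:
        raise ValueError("minimum sequence length must be >= 50")
    if lo > hi:
        raise ValueError("seq_len_range minimum exceeds maximum")
    n_pairs = n_pos + n_neg
    max_pairs = n_prot * (n_prot - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(
            f"requested {n_pairs} pairs but only {max_pairs} distinct "
            f"pairs exist among {n_prot} proteins"
        )

    rng = np.random.default_rng(seed)
    aas = np.array(list(AA_ORDER))
    width = len(str(n_prot - 1))
    sequences = [
        ProteinSequence(
            id=f"prot{i:0{width}d}",
            residues="".join(rng.choice(aas, size=int(rng.integers(lo, hi + 1)))),
        )
        for i in range(n_prot)
    ]
    profile = default_base_profile()
    pssms = {
        seq.id: pseudo_pssm(
            seq, profile, noise_sd=noise_sd, seed=int(rng.integers(2**31))
        )
        for seq in sequences
    }

    # disjoint matching first, random distinct extra pairs if the pool runs out
    ids = [s.id for s in sequences]
    shuffled = list(rng.permutation(ids))
    id_pairs = [
        (shuffled[2 * i], shuffled[2 * i + 1])
        for i in range(min(n_prot // 2, n_pairs))
    ]
    if len(id_pairs) < n_pairs:
        taken = {frozenset(p) for p in id_pairs}
        remaining = [
            p for p in itertools.combinations(ids, 2) if frozenset(p) not in taken
        ]
        extra = rng.choice(len(remaining), size=n_pairs - len(id_pairs), replace=False)
        id_pairs.extend(remaining[i] for i in extra)
        id_pairs = [tuple(id_pairs[i]) for i in rng.permutation(len(id_pairs))]

    motif = _smooth_patch(rng, signal_strength, _MOTIF_WIDTH)
    pairs: list[ProteinPair] = []
    for rank, (a, b) in enumerate(id_pairs):
        if rank < n_pos:
            _insert(pssms[a], motif, rng)
            _insert(pssms[b], motif, rng)
            pairs.append(ProteinPair(a, b, label=1))
        else:
            _insert(pssms[a], _smooth_patch(rng, signal_strength, _MOTIF_WIDTH), rng)
            _insert(pssms[b], _smooth_patch(rng, signal_strength, _MOTIF_WIDTH), rng)
            pairs.append(ProteinPair(a, b, label=0))
    return SyntheticPPI(sequences=sequences, pssms=pssms, pairs=pairs)


def dataset_from_synthetic(synth: SyntheticPPI) -> InteractionDataset:
    """Compute texture descriptors for every protein and assemble (X, Y)."""
    descriptors = {pid: loop_histogram(p) for pid, p in synth.pssms.items()}
    return InteractionDataset(pairs=list(synth.pairs), descriptors=descriptors)


# ---------------------------------------------------------------------------
# Plain-text I/O: pair lists, compartment labels, dataset directories
# ---------------------------------------------------------------------------

def read_pairs_tsv(path: str | Path) -> list[ProteinPair]:
    """3-column TSV (id_a, id_b, label); '#' comments and a header allowed."""
    pairs = []
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            if first_data_line and not tokens[2].lstrip("-").isdigit():
                first_data_line = False
                continue  # header row
            first_data_line = False
            pairs.append(ProteinPair(tokens[0], tokens[1], int(tokens[2])))
    return pairs


def write_pairs_tsv(path: str | Path, pairs: Iterable[ProteinPair]) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlabel\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def read_compartments_tsv(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) != 2:
                raise ValueError(f"{path}: expected 2 columns per line")
            out[tokens[0]] = tokens[1]
    return out


def write_dataset_dir(
    out_dir: str | Path, synth: SyntheticPPI, manifest: dict | None = None
) -> Path:
    """Materialize a synthetic dataset: FASTA + per-protein PSSMs + pairs.tsv."""
    out_dir = Path(out_dir)
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(out_dir / "proteins.fasta", synth.sequences)
    for seq in synth.sequences:
        write_psiblast_pssm(
            pssm_dir / f"{seq.id}.pssm", synth.pssms[seq.id], residues=seq.residues
        )
    write_pairs_tsv(out_dir / "pairs.tsv", synth.pairs)
    if manifest is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return out_dir
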