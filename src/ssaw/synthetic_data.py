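"""Simulated short-read dataset with planted edit-distance cluster structure.

The generator emulates a simulated next-generation-sequencing benchmark:
``n_classes`` centroid reads of fixed length whose pairwise Levenshtein
distance is exactly ``centroid_pairwise_distance``, each surrounded by
``members_per_class - 1`` variants within ``max_member_radius`` edit
operations.  Member edits are substitutions only, so every read keeps the
configured length; with 2 * radius < centroid separation the classes occupy
disjoint edit balls.  Defaults: 8 classes x 65 sequences of length 47,
centroid separation 10, member radius 4 (520 reads in total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics_eval import edit_distance
from .seq_io import DNA, SequenceCollection, SequenceRecord

__all__ = [
    "SimulationConfig",
    "generate_centroids",
    "generate_members",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-cluster read simulator."""

    n_classes: int = 8
    members_per_class: int = 65  # centroid included
    read_length: int = 47
    centroid_pairwise_distance: int = 10
    max_member_radius: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.members_per_class < 1:
            raise ValueError("n_classes and members_per_class must be positive")
        if 2 * self.max_member_radius >= self.centroid_pairwise_distance:
            raise ValueError(
                "disjoint classes need 2 * max_member_radius < "
                "centroid_pairwise_distance"
            )
        if self.read_length <= self.centroid_pairwise_distance:
            raise ValueError("read_length must exceed centroid_pairwise_distance")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _substitute(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with a base guaranteed to differ."""
    out = arr.copy()
    for p in positions:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def generate_centroids(config: SimulationConfig) -> list[SequenceRecord]:
    """Centroid reads with every pairwise Levenshtein distance exact.

    Centroids are found by seeded local search: a candidate starts as the
    first centroid with ``centroid_pairwise_distance`` substitutions, then
    single-base moves reduce the summed Hamming deviation |ham - D| to the
    accepted centroids to zero.  Because Levenshtein <= Hamming, a final
    dynamic-programming pass verifies every pair exactly; candidates whose
    edit distance collapses below D are rejected and re-drawn.  Attempts are
    bounded; exhausting them raises with the attempt count.
    """
    rng = np.random.default_rng(config.seed)
    L, D = config.read_length, config.centroid_pairwise_distance
    max_attempts = 10_000
    attempts = 0

    first = rng.choice(_BASES, size=L)
    accepted = [first]
    while len(accepted) < config.n_classes:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place centroid {len(accepted) + 1} after "
                f"{attempts} attempts"
            )
        attempts += 1
        x = _substitute(first, rng.choice(L, D, replace=False), rng)
        C = np.stack(accepted)
        solved = False
        for _ in range(20_000):
            penalty = np.abs((C != x).sum(axis=1) - D).sum()
            if penalty == 0:
                solved = True
                break
            p = int(rng.integers(L))
            b = rng.choice(_BASES)
            if b == x[p]:
                continue
            old = x[p]
            x[p] = b
            new_penalty = np.abs((C != x).sum(axis=1) - D).sum()
            # accept improvements; sideways moves with small probability
            if new_penalty > penalty or (new_penalty == penalty and rng.random() > 0.3):
                x[p] = old
        if not solved:
            continue
        cand = _to_str(x)
        if all(edit_distance(cand, _to_str(c)) == D for c in accepted):
            accepted.append(x)
    return [
        SequenceRecord(f"class{i + 1}_centroid", _to_str(c))
        for i, c in enumerate(accepted)
    ]


def generate_members(
    centroid: SequenceRecord,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SequenceRecord]:
    """Variant reads within ``max_member_radius`` edits of a centroid.

    Each of the ``members_per_class - 1`` members applies r substitutions at
    distinct positions, r uniform on {1..max_member_radius} (all members
    copy the centroid when the radius is 0); substituted bases always differ
    from the original.  Every member's true Levenshtein distance to the
    centroid is re-verified.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = np.frombuffer(centroid.residues.encode("ascii"), dtype=np.uint8)
    members = []
    for m in range(config.members_per_class - 1):
        if config.max_member_radius == 0:
            variant = base.copy()
        else:
            r = int(rng.integers(1, config.max_member_radius + 1))
            variant = _substitute(base, rng.choice(len(base), r, replace=False), rng)
        seq = _to_str(variant)
        d = edit_distance(seq, centroid.residues)
        if d > config.max_member_radius:  # pragma: no cover - substitutions bound it
            raise RuntimeError(
                f"member exceeded radius: distance {d} > {config.max_member_radius}"
            )
        members.append(SequenceRecord(f"{centroid.id.rsplit('_', 1)[0]}_m{m + 1:03d}", seq))
    return members


def generate_dataset(config: SimulationConfig | None = None) -> SequenceCollection:
    """Full labelled dataset: centroid plus members for every class.

    The default configuration yields 520 reads of length 47 in 8 classes of
    65, labelled ``class1`` .. ``class8``.  Deterministic under the config
    seed (same seed, byte-identical output).
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    centroids = generate_centroids(config)
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for i, centroid in enumerate(centroids):
        label = f"class{i + 1}"
        group = [centroid, *generate_members(centroid, config, rng)]
        records.extend(group)
        labels.update({r.id: label for r in group})
    return SequenceCollection(records, DNA, labels)
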