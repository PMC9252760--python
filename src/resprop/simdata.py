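"""Synthetic annotated protein datasets for training and testing.

The generator emulates the statistical structure the model is meant to
learn, without any claim of biological realism: secondary structure is a
first-order Markov chain over the eight DSSP states (giving segmental runs,
since self-transitions dominate), amino acids are emitted from
state-conditional distributions (well separated by default, so three-state
structure is learnable from sequence alone), backbone dihedrals are drawn
from state-conditional wrapped Gaussians centred on the canonical basins
(helix near (-60, -45), strand near (-120, 130), coil broad), and relative
accessibility from state-conditional Beta distributions (strand most
buried, coil most exposed).  Disordered stretches of geometric length are
placed at the termini and relabelled as exposed coil; disordered and
unknown ('X') positions are excluded from the regression validity mask,
mirroring how unreliable reference values are masked in real training data.

Everything is drawn from a single seeded generator, so a fixed seed
reproduces the dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AMINO_ACIDS,
    Q8_CLASSES,
    ProteinRecord,
    ResidueAnnotations,
    ValidationError,
)

_N_STATES = len(Q8_CLASSES)  # 8
_N_AA = len(AMINO_ACIDS)     # 20
_COIL_IDX = Q8_CLASSES.index("C")


def _default_transition() -> np.ndarray:
    """Self-persistent 8-state chain; leaving mass goes to states in
    proportion to typical occupancy (H, E and C dominate)."""
    persistence = np.array([0.92, 0.70, 0.60, 0.88, 0.55, 0.75, 0.70, 0.82])
    occupancy = np.array([0.30, 0.04, 0.01, 0.22, 0.02, 0.12, 0.08, 0.21])
    mat = np.zeros((_N_STATES, _N_STATES))
    for i in range(_N_STATES):
        off = occupancy.copy()
        off[i] = 0.0
        off /= off.sum()
        mat[i] = off * (1.0 - persistence[i])
        mat[i, i] = persistence[i]
    return mat


def _default_emission() -> np.ndarray:
    """State-conditional amino-acid distributions with a strong three-state
    signal: helix-, strand- and coil-type states each favour a disjoint
    residue group with 85% of the mass."""
    groups = {
        "helix": "ALMEQKR",
        "strand": "VIFYWTC",
        "coil": "GPSNDH",
    }
    state_group = {"H": "helix", "G": "helix", "I": "helix",
                   "E": "strand", "B": "strand",
                   "T": "coil", "S": "coil", "C": "coil"}
    emission = np.zeros((_N_STATES, _N_AA))
    for s_idx, s in enumerate(Q8_CLASSES):
        favoured = [AMINO_ACIDS.index(a) for a in groups[state_group[s]]]
        rest = [i for i in range(_N_AA) if i not in favoured]
        emission[s_idx, favoured] = 0.85 / len(favoured)
        emission[s_idx, rest] = 0.15 / len(rest)
    return emission


#: Per-state (phi, psi) means in degrees: canonical Ramachandran basins.
_DEFAULT_ANGLE_MEANS = np.array([
    (-60.0, -45.0),   # H
    (-60.0, -30.0),   # G
    (-60.0, -50.0),   # I
    (-120.0, 130.0),  # E
    (-110.0, 140.0),  # B
    (-70.0, -10.0),   # T
    (-85.0, 70.0),    # S
    (-75.0, 90.0),    # C
])

_DEFAULT_ANGLE_SDS = np.array([
    (10.0, 10.0), (12.0, 12.0), (12.0, 12.0),
    (15.0, 15.0), (18.0, 18.0),
    (30.0, 30.0), (45.0, 45.0), (55.0, 55.0),
])

#: Per-state Beta(a, b) parameters for RSA: strand buried, coil exposed.
_DEFAULT_RSA_PARAMS = np.array([
    (2.0, 4.0), (2.5, 3.5), (2.0, 4.0),
    (1.5, 5.0), (2.0, 4.0),
    (3.0, 3.0), (3.5, 2.5), (3.5, 2.5),
])


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic annotated-dataset generator."""

    n_sequences: int = 100
    length_range: tuple[int, int] = (50, 150)
    ss_transition: np.ndarray = field(default_factory=_default_transition)
    ss_init: np.ndarray = field(
        default_factory=lambda: np.array([0.30, 0.04, 0.01, 0.22, 0.02, 0.12, 0.08, 0.21])
    )
    aa_emission: np.ndarray = field(default_factory=_default_emission)
    angle_means: np.ndarray = field(default_factory=lambda: _DEFAULT_ANGLE_MEANS.copy())
    angle_sds: np.ndarray = field(default_factory=lambda: _DEFAULT_ANGLE_SDS.copy())
    rsa_params: np.ndarray = field(default_factory=lambda: _DEFAULT_RSA_PARAMS.copy())
    disorder_terminal_prob: float = 0.3
    disorder_mean_len: float = 8.0
    unknown_residue_prob: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        self.ss_transition = np.asarray(self.ss_transition, dtype=np.float64)
        self.ss_init = np.asarray(self.ss_init, dtype=np.float64)
        self.aa_emission = np.asarray(self.aa_emission, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        for name, mat, ncol in (("ss_transition", self.ss_transition, _N_STATES),
                                ("aa_emission", self.aa_emission, _N_AA)):
            if mat.shape != (_N_STATES, ncol):
                raise ValidationError(f"{name} must have shape (8, {ncol})")
            if (mat < 0).any() or (mat > 1).any():
                raise ValidationError(f"{name} entries must be probabilities")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValidationError(f"rows of {name} must sum to 1 within 1e-9")
        if not np.isclose(self.ss_init.sum(), 1.0, atol=1e-9):
            raise ValidationError("ss_init must sum to 1 within 1e-9")
        if not 0 <= self.disorder_terminal_prob <= 1:
            raise ValidationError("disorder_terminal_prob must be in [0, 1]")
        if not 0 <= self.unknown_residue_prob <= 1:
            raise ValidationError("unknown_residue_prob must be in [0, 1]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValidationError(f"invalid length_range {self.length_range}")


def _wrap_degrees(deg: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def _sample_chain(rng: np.random.Generator, trans: np.ndarray,
                  init: np.ndarray, L: int) -> np.ndarray:
    states = np.empty(L, dtype=np.int64)
    cum_init = np.cumsum(init)
    cum_trans = np.cumsum(trans, axis=1)
    u = rng.random(L)
    states[0] = np.searchsorted(cum_init, u[0])
    for t in range(1, L):
        states[t] = np.searchsorted(cum_trans[states[t - 1]], u[t])
    return states


def generate_dataset(config: GeneratorConfig) -> list[tuple[ProteinRecord, ResidueAnnotations]]:
    """Generate annotated synthetic protein records, reproducibly from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dataset = []
    cum_emission = np.cumsum(config.aa_emission, axis=1)
    for idx in range(config.n_sequences):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        q8 = _sample_chain(rng, config.ss_transition, config.ss_init, L)

        aa_idx = np.array([
            np.searchsorted(cum_emission[s], u)
            for s, u in zip(q8, rng.random(L))
        ])
        letters = np.array(list(AMINO_ACIDS))[aa_idx]
        unknown = rng.random(L) < config.unknown_residue_prob
        letters[unknown] = "X"

        # disordered stretches at the termini, geometric length, relabelled
        # as exposed coil
        disorder = np.zeros(L, dtype=bool)
        p_geom = min(1.0, 1.0 / max(config.disorder_mean_len, 1.0))
        for terminus in ("N", "C"):
            if rng.random() < config.disorder_terminal_prob:
                run = min(int(rng.geometric(p_geom)), max(L // 3, 1))
                if terminus == "N":
                    disorder[:run] = True
                else:
                    disorder[L - run:] = True
        q8[disorder] = _COIL_IDX

        phi = rng.normal(config.angle_means[q8, 0], config.angle_sds[q8, 0])
        psi = rng.normal(config.angle_means[q8, 1], config.angle_sds[q8, 1])
        rsa = rng.beta(config.rsa_params[q8, 0], config.rsa_params[q8, 1])
        rsa[disorder] = rng.beta(5.0, 2.0, disorder.sum())

        record = ProteinRecord(id=f"syn{idx:05d}", sequence="".join(letters))
        ann = ResidueAnnotations(
            q8=q8,
            disorder=disorder,
            rsa=rsa,
            phi=_wrap_degrees(phi),
            psi=_wrap_degrees(psi),
            valid_regression=~(disorder | unknown),
        )
        dataset.append((record, ann))
    return dataset


def majority_class_rate(dataset, three_state: bool = True) -> float:
    """Rate of the most frequent (Q3 by default) class across the dataset —
    the accuracy of a constant predictor, the baseline a learned model must
    beat."""
    labels = np.concatenate([
        ann.q3 if three_state else ann.q8 for _, ann in dataset
    ])
    return float(np.bincount(labels).max() / len(labels))


def write_reference_tables(dataset, directory) -> tuple[str, str]:
    """Write the dataset as FASTA + per-residue annotation table.

    Returns the two file paths; the directory is created if needed.  The
    files round-trip losslessly through :mod:`resprop.io` readers.
    """
    from . import io as rio
    from pathlib import Path

    if len(dataset) == 0:
        raise ValidationError("cannot write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "sequences.fasta"
    table = directory / "annotations.csv"
    rio.write_fasta([rec for rec, _ in dataset], fasta)
    rio.write_annotations(dataset, table)
    return str(fasta), str(table)
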