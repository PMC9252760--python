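"""Domain types and shared definitions.

The package predicts, for every residue of a protein sequence, six local
structural properties: eight-state (Q8) and three-state (Q3) secondary
structure, structural disorder, relative solvent accessibility (RSA, the
solvent-exposed fraction in [0, 1]), and the backbone dihedral angles phi
and psi. Absolute accessibility (ASA, in Å²) is derived from RSA by
multiplying with a residue-specific maximum.

This module holds the alphabets, the label conventions, the model/training
configuration with its defaults, and basic input validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np

#: The 20 canonical amino-acid letters, in the column order used by the
#: one-hot encoding.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Placeholder for an unknown residue.  Any other non-canonical letter is an
#: input error rather than being silently remapped.
UNKNOWN_RESIDUE = "X"

ALPHABET = AMINO_ACIDS + UNKNOWN_RESIDUE

AA_INDEX: Mapping[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: DSSP eight-state secondary-structure classes, in head-output order.
Q8_CLASSES = "HGIEBTSC"
Q8_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(Q8_CLASSES)}

#: Three-state classes, in head-output order.
Q3_CLASSES = ("helix", "strand", "coil")
Q3_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(Q3_CLASSES)}

#: Fixed Q8 -> Q3 collapse: 3-10/alpha/pi helices to helix, extended strand
#: and isolated beta-bridge to strand, turns/bends/loops to coil.
Q8_TO_Q3: Mapping[str, str] = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "coil", "S": "coil", "C": "coil",
}

# Theoretical maximum accessible surface areas (Å²) per residue, Tien et al.
# scale.  Users may substitute another scale via configuration.
DEFAULT_MAX_ASA: Mapping[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "K": 236.0, "L": 201.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Default maximum ASA assigned to unknown ('X') residues: the mean of the
#: 20 canonical values, rounded to one decimal.
DEFAULT_MAX_ASA_UNKNOWN = round(
    float(np.mean(list(DEFAULT_MAX_ASA.values()))), 1
)

#: Default sequence-length limits (configurable).
MIN_SEQ_LEN = 10
MAX_SEQ_LEN = 5000

#: Default cap on total residues in one job (configurable).
MAX_TOTAL_RESIDUES = 10_000_000
#: Default cap on the number of sequences in one job.
MAX_SEQUENCES = 10_000


class ValidationError(ValueError):
    """An input record violated the alphabet or length contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    ``sequence`` is over the 20 canonical letters plus ``X`` for unknown;
    use :func:`validate_record` to normalise case and enforce the alphabet.
    """

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueAnnotations:
    """Per-residue reference labels with validity masks.

    Attributes
    ----------
    q8
        Integer class indices into :data:`Q8_CLASSES`, shape ``(L,)``.
    disorder
        Boolean flag per residue, shape ``(L,)``.
    rsa
        Relative solvent accessibility in ``[0, 1]``, shape ``(L,)``.
    phi, psi
        Backbone dihedrals in degrees in ``(-180, 180]``, shape ``(L,)``.
    valid_regression
        Boolean mask, False where the residue is disordered or unknown;
        RSA/phi/psi losses and metrics are restricted to True positions.
    """

    q8: np.ndarray
    disorder: np.ndarray
    rsa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    valid_regression: np.ndarray

    def __post_init__(self) -> None:
        self.q8 = np.asarray(self.q8, dtype=np.int64)
        self.disorder = np.asarray(self.disorder, dtype=bool)
        self.rsa = np.asarray(self.rsa, dtype=np.float64)
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.psi = np.asarray(self.psi, dtype=np.float64)
        self.valid_regression = np.asarray(self.valid_regression, dtype=bool)
        L = len(self.q8)
        for name in ("disorder", "rsa", "phi", "psi", "valid_regression"):
            if len(getattr(self, name)) != L:
                raise ValidationError(
                    f"annotation field {name!r} has length "
                    f"{len(getattr(self, name))}, expected {L}"
                )

    def __len__(self) -> int:
        return len(self.q8)

    @property
    def q3(self) -> np.ndarray:
        """Integer Q3 classes derived from ``q8`` via the fixed collapse."""
        return Q8_TO_Q3_IDX[self.q8]

    @property
    def q8_letters(self) -> list[str]:
        return [Q8_CLASSES[i] for i in self.q8]


#: Integer lookup for the Q8 -> Q3 collapse, aligned with Q8_CLASSES order.
Q8_TO_Q3_IDX = np.array(
    [Q3_INDEX[Q8_TO_Q3[c]] for c in Q8_CLASSES], dtype=np.int64
)


def collapse_q8_to_q3(q8_labels: Sequence[str]) -> list[str]:
    """Collapse eight-state labels to three-state labels.

    H, G, I -> helix; E, B -> strand; T, S, C -> coil.

    Raises
    ------
    ValidationError
        If a label is not one of the eight class letters.
    """
    out = []
    for lab in q8_labels:
        try:
            out.append(Q8_TO_Q3[lab])
        except KeyError:
            raise ValidationError(
                f"unknown secondary-structure class {lab!r}; "
                f"expected one of {Q8_CLASSES}"
            ) from None
    return out


def validate_record(
    record: ProteinRecord,
    min_len: int = MIN_SEQ_LEN,
    max_len: int = MAX_SEQ_LEN,
) -> ProteinRecord:
    """Validate a protein record, normalising the sequence to upper case.

    Accepts the record iff its (uppercased) sequence uses only the 21-letter
    alphabet and its length lies in ``[min_len, max_len]``.  Validation is
    idempotent: an already-valid record is returned unchanged.

    Raises
    ------
    ValidationError
        Naming the violated limit, or the position and character of the
        first illegal letter.
    """
    seq = record.sequence.upper()
    L = len(seq)
    if L < min_len:
        raise ValidationError(
            f"sequence {record.id!r} has length {L}, "
            f"below the minimum of {min_len} residues"
        )
    if L > max_len:
        raise ValidationError(
            f"sequence {record.id!r} has length {L}, "
            f"above the maximum of {max_len} residues"
        )
    for pos, ch in enumerate(seq):
        if ch not in AA_INDEX and ch != UNKNOWN_RESIDUE:
            raise ValidationError(
                f"sequence {record.id!r} has illegal character {ch!r} "
                f"at position {pos + 1}"
            )
    if seq == record.sequence:
        return record
    return replace(record, sequence=seq)


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the published method: two parallel wide-kernel 1D
    convolutions (32 channels, kernels 129 and 257 with 'same' paddings 64
    and 128), concatenation with the input, batch normalisation, a 2-layer
    biLSTM with hidden size 1024 per direction, a fully connected layer and
    six linear task heads; Adam with lr 5e-4, eps 1e-8, betas (0.9, 0.99),
    batch size 15, early-stopping patience 3; multi-task loss weights
    1, 5, 5, 100, 5, 5 for Q8, Q3, disorder, RSA, phi, psi.
    """

    input_dim: int = 20
    cnn_channels: int = 32
    kernel_sizes: tuple[int, int] = (129, 257)
    paddings: tuple[int, int] = (64, 128)
    lstm_hidden: int = 1024
    lstm_layers: int = 2
    dropout_p: float = 0.5
    fc_width: int = 2048
    downstream: str = "cnn_bilstm"  # or "transformer"
    transformer_heads: int = 8
    transformer_layers: int = 2
    transformer_dim: int = 128
    loss_weights: tuple[float, ...] = (1.0, 5.0, 5.0, 100.0, 5.0, 5.0)
    lr: float = 5e-4
    adam_eps: float = 1e-8
    adam_betas: tuple[float, float] = (0.9, 0.99)
    weight_decay: float = 0.0
    batch_size: int = 15
    patience: int = 3
    max_epochs: int = 100
    grad_clip: float | None = None
    seed: int = 0
    max_asa: dict = field(default_factory=lambda: dict(DEFAULT_MAX_ASA))
    max_asa_unknown: float = DEFAULT_MAX_ASA_UNKNOWN

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(self.kernel_sizes)
        self.paddings = tuple(self.paddings)
        self.adam_betas = tuple(self.adam_betas)
        self.loss_weights = tuple(float(w) for w in self.loss_weights)
        self.validate()

    def validate(self) -> None:
        for name in ("input_dim", "cnn_channels", "lstm_hidden",
                     "lstm_layers", "fc_width", "transformer_heads",
                     "transformer_layers", "transformer_dim", "batch_size",
                     "patience", "max_epochs"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValidationError(f"dropout_p must be in [0, 1), got {self.dropout_p}")
        if len(self.loss_weights) != 6 or any(w < 0 for w in self.loss_weights):
            raise ValidationError(
                "loss_weights must be six nonnegative reals, got "
                f"{self.loss_weights!r}"
            )
        if self.downstream not in ("cnn_bilstm", "transformer"):
            raise ValidationError(
                f"downstream must be 'cnn_bilstm' or 'transformer', "
                f"got {self.downstream!r}"
            )
        for k, p in zip(self.kernel_sizes, self.paddings):
            if k % 2 != 1 or p != (k - 1) // 2:
                raise ValidationError(
                    f"kernel {k} with padding {p} does not preserve length; "
                    "kernels must be odd with padding (k-1)//2"
                )
        for letter, area in self.max_asa.items():
            if not area > 0:
                raise ValidationError(
                    f"max ASA for {letter!r} must be strictly positive, got {area}"
                )

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})


def max_asa_vector(sequence: str, table: Mapping[str, float] | None = None,
                   unknown_default: float | None = None) -> np.ndarray:
    """Per-residue maximum ASA (Å²) for a sequence.

    Unknown ('X') residues use ``unknown_default``; a canonical residue
    missing from the table raises.
    """
    if table is None:
        table = DEFAULT_MAX_ASA
    if unknown_default is None:
        unknown_default = DEFAULT_MAX_ASA_UNKNOWN
    out = np.empty(len(sequence), dtype=np.float64)
    for i, ch in enumerate(sequence):
        if ch == UNKNOWN_RESIDUE:
            out[i] = unknown_default
        elif ch in table:
            out[i] = table[ch]
        else:
            raise ValidationError(
                f"residue {ch!r} missing from the maximum-ASA table "
                "and no default is configured"
            )
    return out
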