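"""Validated domain types and CSV I/O for CDR3β–peptide binding data.

The package works on a single atomic record: one TCR CDR3β amino-acid
sequence paired with one peptide (epitope) sequence and, for labeled data,
a binary binding label (1 = binds, 0 = does not). Only the CDR3β loop of
the TCR β-chain is used to represent the receptor; no MHC, α-chain or V/J
gene information enters the model.

CSV schema: lowercase columns ``cdr3b``, ``peptide`` and (for labeled data)
``label``. Common header aliases (``CDR3``, ``Peptide``, ``Label`` ...) are
mapped automatically. Background repertoires are one sequence per line
(plain text) or a one-column CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Admissible length windows per sequence role (inclusive).
#: CDR3β loops are typically 8–20 residues; peptides span the ~9-mer
#: MHC-I and ~15-mer MHC-II regimes, so both windows carry margin.
LENGTH_BOUNDS = {"cdr3": (6, 30), "peptide": (7, 30)}

_HEADER_ALIASES = {
    "cdr3": "cdr3b",
    "cdr3b": "cdr3b",
    "cdr3beta": "cdr3b",
    "tcr": "cdr3b",
    "peptide": "peptide",
    "epitope": "peptide",
    "antigen": "peptide",
    "label": "label",
    "binder": "label",
}


class SequenceError(ValueError):
    """A raw string failed amino-acid sequence validation."""


def validate_sequence(raw: str, role: str, bounds: dict | None = None) -> str:
    """Validate and normalize an amino-acid sequence for a given role.

    Uppercases the input, checks every character against the 20-letter
    standard alphabet and enforces the role's length window.

    Parameters
    ----------
    raw : str
        Candidate sequence, any case.
    role : {"cdr3", "peptide"}
        Determines the admissible length window.
    bounds : dict, optional
        Override of :data:`LENGTH_BOUNDS`.

    Returns
    -------
    str
        The uppercase-normalized sequence. Idempotent: validating the
        output returns an equal value.
    """
    if role not in ("cdr3", "peptide"):
        raise ValueError(f"unknown sequence role: {role!r}")
    if not isinstance(raw, str):
        raise SequenceError(f"sequence must be text, got {type(raw).__name__}")
    seq = raw.strip().upper()
    if not seq:
        raise SequenceError(f"empty {role} sequence")
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in _AA_SET]
    if bad:
        detail = ", ".join(f"{c!r} at position {i}" for i, c in bad)
        raise SequenceError(f"invalid amino-acid character(s) in {role}: {detail}")
    lo, hi = (bounds or LENGTH_BOUNDS)[role]
    if not lo <= len(seq) <= hi:
        raise SequenceError(
            f"{role} length {len(seq)} outside admissible range [{lo}, {hi}]: {seq}"
        )
    return seq


@dataclass(frozen=True)
class BindingPair:
    """One CDR3β–peptide record with an optional binary binding label."""

    cdr3b: str
    peptide: str
    label: int | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @classmethod
    def validated(cls, cdr3b: str, peptide: str, label: int | None = None) -> "BindingPair":
        return cls(validate_sequence(cdr3b, "cdr3"), validate_sequence(peptide, "peptide"), label)


@dataclass
class BindingDataset:
    """Ordered collection of :class:`BindingPair` with a provenance tag."""

    pairs: list[BindingPair] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[BindingPair]:
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    @property
    def labels(self) -> list[int | None]:
        return [p.label for p in self.pairs]

    def positives(self) -> "BindingDataset":
        return BindingDataset([p for p in self.pairs if p.label == 1], self.provenance)

    def negatives(self) -> "BindingDataset":
        return BindingDataset([p for p in self.pairs if p.label == 0], self.provenance)

    def is_labeled(self) -> bool:
        return bool(self.pairs) and all(p.label is not None for p in self.pairs)

    def peptides(self) -> set[str]:
        return {p.peptide for p in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        cols = {"cdr3b": [p.cdr3b for p in self.pairs], "peptide": [p.peptide for p in self.pairs]}
        if any(p.label is not None for p in self.pairs):
            cols["label"] = [p.label for p in self.pairs]
        return pd.DataFrame(cols)


@dataclass
class BackgroundRepertoire:
    """Background TCR set used for percentile binding-rank computation.

    The reference protocol draws 1000 CD4 TCRs at random; ``size`` always
    equals the number of stored sequences.
    """

    tcrs: list[str]

    def __post_init__(self):
        if not self.tcrs:
            raise ValueError("background repertoire must be nonempty")

    @property
    def size(self) -> int:
        return len(self.tcrs)


def _canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower().replace("_", "").replace(" ", "")
        if key in _HEADER_ALIASES:
            mapping[col] = _HEADER_ALIASES[key]
    return df.rename(columns=mapping)


def read_pairs_csv(
    path: str | Path,
    require_label: bool = False,
    permissive: bool = False,
) -> BindingDataset:
    """Read a CSV of CDR3β/peptide pairs into a validated dataset.

    Every row passes :func:`validate_sequence`; exact duplicate
    ``(cdr3b, peptide, label)`` rows are dropped keeping the first
    occurrence. Rows carrying the same (cdr3b, peptide) with *conflicting*
    labels are rejected — a label conflict indicates a curation error, not
    something to resolve silently.

    Parameters
    ----------
    path : path-like
        CSV with a header containing ``cdr3b`` and ``peptide`` columns
        (common aliases accepted), plus ``label`` if ``require_label``.
    require_label : bool
        Demand a label column with binary values.
    permissive : bool
        Skip invalid rows (logged) instead of raising.
    """
    path = Path(path)
    df = _canonical_columns(pd.read_csv(path, dtype=str, keep_default_na=False))
    for col in ("cdr3b", "peptide") + (("label",) if require_label else ()):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    has_label = "label" in df.columns

    pairs: list[BindingPair] = []
    errors: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            label = None
            if has_label:
                raw = str(getattr(row, "label")).strip()
                if raw == "" and not require_label:
                    label = None
                elif raw in ("0", "1"):
                    label = int(raw)
                elif raw in ("0.0", "1.0"):
                    label = int(float(raw))
                else:
                    raise SequenceError(f"unparseable label {raw!r}")
            pairs.append(BindingPair.validated(row.cdr3b, row.peptide, label))
        except (SequenceError, ValueError) as exc:
            errors.append(f"row {idx}: {exc}")
    if errors and not permissive:
        raise ValueError(f"{len(errors)} invalid row(s) in {path.name}: " + "; ".join(errors[:10]))
    if errors:
        logger.warning("%s: skipped %d invalid row(s)", path.name, len(errors))

    # dedup exact triples, keep first; reject label conflicts
    seen: dict[tuple, int] = {}
    by_pair_labels: dict[tuple[str, str], set] = {}
    unique: list[BindingPair] = []
    dropped = 0
    for p in pairs:
        key = (p.cdr3b, p.peptide, p.label)
        if key in seen:
            dropped += 1
            continue
        seen[key] = 1
        unique.append(p)
        if p.label is not None:
            by_pair_labels.setdefault((p.cdr3b, p.peptide), set()).add(p.label)
    conflicts = [k for k, v in by_pair_labels.items() if len(v) > 1]
    if conflicts:
        listing = "; ".join(f"{c}/{pep}" for c, pep in conflicts[:10])
        raise ValueError(
            f"{len(conflicts)} pair(s) with conflicting labels in {path.name}: {listing}"
        )
    logger.info("%s: read %d rows, kept %d pairs, dropped %d duplicates",
                path.name, len(pairs), len(unique), dropped)
    return BindingDataset(unique, provenance=str(path))


def write_pairs_csv(dataset: BindingDataset, path: str | Path) -> None:
    """Write a dataset back to the canonical CSV schema."""
    dataset.to_frame().to_csv(path, index=False)


def write_predictions_csv(
    dataset: BindingDataset,
    scores: Sequence[float],
    path: str | Path,
    ranks: Sequence | None = None,
) -> None:
    """Write per-pair binding probabilities (and optional rank results).

    Output columns: ``cdr3b, peptide, score`` plus ``rank, category`` when
    rank results are supplied. Row order follows the input dataset.
    """
    if len(scores) != len(dataset):
        raise ValueError(f"length mismatch: {len(dataset)} pairs vs {len(scores)} scores")
    bad = [s for s in scores if not (0.0 <= float(s) <= 1.0)]
    if bad:
        raise ValueError(f"scores outside [0, 1]: {bad[:5]}")
    df = pd.DataFrame({
        "cdr3b": [p.cdr3b for p in dataset],
        "peptide": [p.peptide for p in dataset],
        "score": [float(s) for s in scores],
    })
    if ranks is not None:
        if len(ranks) != len(dataset):
            raise ValueError("length mismatch between pairs and ranks")
        df["rank"] = [r.rank for r in ranks]
        df["category"] = [r.category for r in ranks]
    df.to_csv(path, index=False)


def read_repertoire(path: str | Path) -> BackgroundRepertoire:
    """Read a TCR repertoire from plain text (one per line) or one-column CSV."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty repertoire file: {path}")
    first_key = lines[0].strip().lower().replace("_", "").replace(" ", "")
    if _HEADER_ALIASES.get(first_key) == "cdr3b":  # header row
        lines = lines[1:]
    tcrs = [validate_sequence(ln.split(",")[0], "cdr3") for ln in lines]
    return BackgroundRepertoire(tcrs)


def write_repertoire(rep: BackgroundRepertoire | Iterable[str], path: str | Path) -> None:
    tcrs = rep.tcrs if isinstance(rep, BackgroundRepertoire) else list(rep)
    Path(path).write_text("\n".join(tcrs) + "\n")
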