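"""Synthetic PSSMs and labeled, class-imbalanced datasets.

Real profile data require PSI-BLAST runs against a sequence database; this
module generates integer-rounded Gaussian PSSMs whose class signal lives in
PSSM column space — positives get a mean shift on a chosen subset of residue
columns — so the whole pipeline (parsing, LAG pooling, PCA, WELM) is
exercised end to end. The default imbalance of one positive per 7.8
negatives mirrors the yeast benchmark composition (710 SIPs vs 5511
non-SIPs); lengths are drawn uniformly from a plausible protein-length
range. The simulation makes no attempt at biological realism (no
phylogenetic correlation between positions, no gap or domain structure).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sipwelm.pssm_io import (
    PSIBLAST_COLUMN_ORDER,
    PSSM,
    ProteinSequence,
    write_ascii_pssm,
    write_fasta,
)

#: Yeast benchmark imbalance: 5511 non-SIPs / 710 SIPs.
DEFAULT_IMBALANCE = 5511 / 710  # ~7.76 negatives per positive


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic labeled PSSM dataset.

    Defaults give a miniature of the yeast benchmark: 40 positives and 312
    negatives (1:7.8), lengths 50-400 residues, unit base score with
    noise_sd 2.0 (log-odds scores are small integers), and a +2.0 mean
    shift on four residue columns for positives.
    """

    n_pos: int = 40
    n_neg: int = 312
    length_range: tuple[int, int] = (50, 400)
    class_shift: float = 2.0
    shift_columns: tuple[int, ...] = (0, 5, 10, 15)
    base_mean: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class counts must be non-negative")
        lmin, lmax = self.length_range
        if lmin < 20 or lmax < lmin:
            raise ValueError("length_range must satisfy 20 <= Lmin <= Lmax")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        bad = [c for c in self.shift_columns if not 0 <= c < 20]
        if bad:
            raise ValueError(f"shift column indices out of range: {bad}")


def generate_synthetic_pssm(
    L: int,
    base_mean: float = 0.0,
    noise_sd: float = 2.0,
    shift_columns: tuple[int, ...] = (),
    shift: float = 0.0,
    seed: int = 0,
    protein_id: str = "synthetic",
) -> PSSM:
    """One synthetic PSSM: iid Normal(base_mean, noise_sd) entries, +shift on
    the listed columns, rounded to integers to mimic log-odds files."""
    if L < 20:
        raise ValueError(f"L must be >= 20, got {L}")
    bad = [c for c in shift_columns if not 0 <= c < 20]
    if bad:
        raise ValueError(f"shift column indices out of range: {bad}")
    rng = np.random.default_rng(seed)
    scores = rng.normal(base_mean, noise_sd, size=(L, 20))
    for c in shift_columns:
        scores[:, c] += shift
    scores = np.round(scores)
    return PSSM(
        protein_id=protein_id,
        scores=scores,
        column_order=PSIBLAST_COLUMN_ORDER,
        source="synthetic",
    )


def generate_dataset(spec: SyntheticSpec) -> list[tuple[PSSM, int]]:
    """Labeled PSSM list: exactly n_pos positives (+1, with the class shift)
    followed by n_neg negatives (-1, without); deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[PSSM, int]] = []
    lmin, lmax = spec.length_range
    for label, count, cols, shift in (
        (1, spec.n_pos, spec.shift_columns, spec.class_shift),
        (-1, spec.n_neg, (), 0.0),
    ):
        tag = "pos" if label == 1 else "neg"
        for i in range(count):
            L = int(rng.integers(lmin, lmax + 1))
            pssm = generate_synthetic_pssm(
                L,
                base_mean=spec.base_mean,
                noise_sd=spec.noise_sd,
                shift_columns=cols,
                shift=shift,
                seed=int(rng.integers(0, 2**31)),
                protein_id=f"{tag}{i:04d}",
            )
            out.append((pssm, label))
    return out


def _pssm_to_sequence(pssm: PSSM) -> ProteinSequence:
    """Plausible query sequence: per-position argmax residue of the profile."""
    idx = np.argmax(pssm.scores, axis=1)
    residues = "".join(pssm.column_order[j] for j in idx)
    return ProteinSequence(id=pssm.protein_id, residues=residues)


def write_fixture_tree(spec: SyntheticSpec, out_dir) -> Path:
    """Materialize a dataset on disk: ``pssms/<id>.pssm`` files, a combined
    FASTA, a two-column labels CSV and a manifest recording the seed."""
    out_dir = Path(out_dir)
    pssm_dir = out_dir / "pssms"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(spec)
    sequences = []
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein_id", "label"])
        for pssm, label in data:
            write_ascii_pssm(pssm, pssm_dir / f"{pssm.protein_id}.pssm")
            sequences.append(_pssm_to_sequence(pssm))
            writer.writerow([pssm.protein_id, label])
    write_fasta(sequences, out_dir / "sequences.fasta")
    with open(out_dir / "manifest.txt", "w") as fh:
        fh.write(f"seed: {spec.seed}\n")
        fh.write(f"n_pos: {spec.n_pos}\nn_neg: {spec.n_neg}\n")
        fh.write(f"length_range: {spec.length_range}\n")
        fh.write(f"class_shift: {spec.class_shift}\n")
        fh.write(f"shift_columns: {spec.shift_columns}\n")
        fh.write(f"base_mean: {spec.base_mean}\nnoise_sd: {spec.noise_sd}\n")
    return out_dir
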