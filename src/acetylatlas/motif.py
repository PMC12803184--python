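"""Flanking-sequence motifs: frequency matrices, information content, logos.

Acetyl-site flanks (the +/-7-residue window around the modified lysine)
are compared against the background of all lysines in the proteome.
Per-position amino-acid counts become probability matrices; information
content per position is computed against a uniform 20-residue background;
foreground/background comparison uses pseudocounted log2 ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .config import PipelineConfig
from .ingest import SiteRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")
PAD = "_"          # terminal padding, excluded from all frequencies


@dataclass
class LogoMatrix:
    """Position x residue counts, probabilities, and information content.

    Positions run -radius..+radius with the modified residue at 0.
    Probabilities at each position are over non-padding characters only.
    """

    counts: pd.DataFrame           # positions x 20 residues
    probabilities: pd.DataFrame
    information: pd.Series         # bits per position, vs uniform background

    @property
    def positions(self) -> list[int]:
        return list(self.counts.index)


def extract_background_flanks(
    fasta_path: str | Path, cfg: PipelineConfig | None = None
) -> list[str]:
    """One padded flank window per lysine in every proteome sequence."""
    cfg = cfg or PipelineConfig()
    r = cfg.flank_radius
    flanks: list[str] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        for i, aa in enumerate(seq):
            if aa != "K":
                continue
            left = seq[max(0, i - r): i].rjust(r, PAD)
            right = seq[i + 1: i + 1 + r].ljust(r, PAD)
            flanks.append(left + "K" + right)
    return flanks


def site_flanks(records: list[SiteRecord]) -> list[str]:
    """Flank windows carried by site records, uppercased."""
    return [rec.flank.upper() for rec in records if rec.flank]


def build_logo(flanks: list[str], cfg: PipelineConfig | None = None) -> LogoMatrix:
    """Count residues per position and derive probabilities and IC.

    IC_j = log2(20) + sum_a p_aj * log2(p_aj), in bits; padding and any
    non-standard residue characters are skipped (with a warning for the
    latter) and do not dilute the frequencies.
    """
    cfg = cfg or PipelineConfig()
    if not flanks:
        raise ValueError("cannot build a logo from zero flanks")
    width = len(flanks[0])
    if any(len(f) != width for f in flanks):
        raise ValueError("flanks must have uniform length")
    r = width // 2
    positions = list(range(-r, width - r))
    counts = pd.DataFrame(0, index=pd.Index(positions, name="position"),
                          columns=AMINO_ACIDS, dtype=int)
    aa_set = set(AMINO_ACIDS)
    skipped = 0
    arr = np.array([list(f) for f in flanks])
    for j, pos in enumerate(positions):
        col = arr[:, j]
        for aa, n in zip(*np.unique(col, return_counts=True)):
            if aa in aa_set:
                counts.at[pos, aa] = int(n)
            elif aa != PAD:
                skipped += int(n)
    if skipped:
        logger.warning("skipped %d non-standard residue character(s)", skipped)
    totals = counts.sum(axis=1).astype(float)
    probs = counts.div(totals.where(totals > 0, 1.0), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs.to_numpy() > 0,
                         probs.to_numpy() * np.log2(probs.to_numpy()), 0.0)
    ic = pd.Series(np.log2(20.0) + plogp.sum(axis=1), index=counts.index)
    ic[totals == 0] = 0.0
    return LogoMatrix(counts, probs, ic)


def compare_logos(
    foreground: LogoMatrix,
    background: LogoMatrix,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-position per-residue log2 enrichment of foreground vs background.

    Both matrices are re-normalized with a pseudocount (default 0.5 per
    residue per position) so absent residues stay finite.  The center
    position (all-K in both sets) is excluded.
    """
    cfg = cfg or PipelineConfig()
    if foreground.positions != background.positions:
        raise ValueError("logo position ranges do not match")
    pc = cfg.logo_pseudocount

    def smoothed(logo: LogoMatrix) -> pd.DataFrame:
        c = logo.counts.astype(float) + pc
        return c.div(c.sum(axis=1), axis=0)

    ratio = np.log2(smoothed(foreground) / smoothed(background))
    return ratio.drop(index=0)


def top_enriched_residue(enrichment: pd.DataFrame) -> tuple[int, str, float]:
    """(position, residue, log2 ratio) of the single most enriched cell."""
    stacked = enrichment.stack()
    pos, aa = stacked.idxmax()
    return int(pos), str(aa), float(stacked.max())
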