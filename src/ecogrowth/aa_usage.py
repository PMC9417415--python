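"""Proteome-wide amino-acid usage with expression weighting.

Counts each of the 20 standard amino acids across every annotated protein
of a GenBank genome record and computes relative abundances, optionally
weighted by per-gene expression levels as a copy-number proxy for the
growing cell's proteome.  Branched-chain amino-acid (Ile/Leu/Val)
enrichment is reported against the uniform theoretical expectation of
1/20 per amino acid (5 %) and 3/20 for the BCAA aggregate (15 %).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
BCAA = ("I", "L", "V")

#: Uniform-usage expectations: one of 20 amino acids, three of 20 for BCAAs.
THEORETICAL_SINGLE = 1 / 20
THEORETICAL_BCAA = 3 / 20


@dataclass
class ProteomeCounts:
    """Per-gene amino-acid counts; ``counts`` rows are genes, columns the 20 AAs."""

    counts: pd.DataFrame
    skipped_symbols: dict

    @property
    def lengths(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class UsageProfile:
    """Relative abundance of the 20 amino acids (fractions sum to 1)."""

    fractions: pd.Series
    weighting: str                    # 'unweighted' | 'expression-weighted'

    @property
    def bcaa(self) -> float:
        return float(self.fractions[list(BCAA)].sum())


def _gene_id(feature, fallback: str) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return fallback


def _translation(feature, record: SeqRecord) -> str:
    if "translation" in feature.qualifiers:
        return feature.qualifiers["translation"][0]
    return str(feature.extract(record.seq).translate(to_stop=True))


def count_amino_acids(record: SeqRecord | str | Path) -> ProteomeCounts:
    """Count the 20 standard amino acids over every CDS of a genome record.

    Accepts a Biopython ``SeqRecord`` or a path to a GenBank file.
    Stop symbols and non-standard residues (U, X, B, Z, ...) are excluded
    from the counts with a logged tally.
    """
    if not isinstance(record, SeqRecord):
        record = SeqIO.read(str(record), "genbank")
    rows, skipped = {}, {}
    n_cds = 0
    for i, feature in enumerate(record.features):
        if feature.type != "CDS":
            continue
        n_cds += 1
        protein = _translation(feature, record)
        gid = _gene_id(feature, f"cds_{i}")
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for residue in protein.upper():
            if residue in counts:
                counts[residue] += 1
            else:
                skipped[residue] = skipped.get(residue, 0) + 1
        rows[gid] = counts
    if n_cds == 0:
        raise ValueError(f"record {record.id!r} contains no CDS features")
    if skipped:
        logger.info("excluded non-standard symbols: %s", skipped)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(AMINO_ACIDS))
    counts.index.name = "gene"
    return ProteomeCounts(counts=counts, skipped_symbols=skipped)


def relative_abundance(counts: ProteomeCounts,
                       expression: pd.Series | dict | None = None) -> UsageProfile:
    """Relative amino-acid abundance, optionally expression-weighted.

    Unweighted: total counts over the grand total.  Weighted: each gene's
    counts are multiplied by its expression level (a per-protein copy-number
    proxy), i.e. ``sum_g level_g * counts_g / sum_g level_g * length_g``.
    Replicate transcript measurements should be averaged per gene upstream.
    """
    table = counts.counts
    if expression is None:
        totals = table.sum(axis=0)
        return UsageProfile(fractions=totals / totals.sum(), weighting="unweighted")
    levels = pd.Series(expression, dtype=float)
    missing = table.index.difference(levels.index)
    if len(missing):
        raise ValueError(f"expression levels missing for genes: {list(missing)[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    levels = levels.loc[table.index]
    if (levels < 0).any():
        raise ValueError("expression levels must be non-negative")
    if (levels == 0).all():
        raise ValueError("all expression levels are zero; weighting undefined")
    weighted = table.mul(levels, axis=0).sum(axis=0)
    return UsageProfile(fractions=weighted / weighted.sum(),
                        weighting="expression-weighted")


def bcaa_enrichment(profile: UsageProfile) -> dict:
    """Observed-over-theoretical enrichment of Ile and of the BCAA aggregate."""
    return {
        "ile_fraction": float(profile.fractions["I"]),
        "ile_theoretical": THEORETICAL_SINGLE,
        "ile_ratio": float(profile.fractions["I"] / THEORETICAL_SINGLE),
        "bcaa_fraction": profile.bcaa,
        "bcaa_theoretical": THEORETICAL_BCAA,
        "bcaa_ratio": profile.bcaa / THEORETICAL_BCAA,
    }


def read_expression_tsv(path) -> pd.Series:
    """Two-column expression TSV (gene id, level) -> per-gene level Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "level"],
                     comment="#")
    return df.set_index("gene")["level"].astype(float)
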