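"""Bundled assay definitions, published characterization tables, and
synthetic reference templates.

The CSV tables ship the published wet-lab characterization data for the
trout/salmon myoglobin duplex panel — calibration concentrations, the
verification mixtures with ddPCR and qPCR results, and the low-fraction
sensitivity series — so the calibration, verification and LOD/LOQ rules can
be exercised on real printed numbers without any instrument export.

The reference templates returned by :func:`synthetic_templates` are
SYNTHETIC: the true GenBank mRNA records are not redistributed here, so each
template is a deterministic random sequence into which the real primer and
probe sites of one assay are planted at spacings giving the documented
amplicon lengths (93 bp for Atlantic salmon, 141 bp for rainbow trout).
They exercise the in-silico PCR machinery and reproduce the amplicon lengths
by construction; they are not the biological sequences.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .assays import Assay

_BASES = np.array(list("ACGT"))


def _read_text(name: str) -> str:
    return (resources.files("salmoquant") / "data" / name).read_text()


def load_assays() -> list[Assay]:
    """The bundled duplex myoglobin panel (salmon on HEX, trout on FAM)."""
    doc = yaml.safe_load(_read_text("assays.yaml"))
    return [Assay(**entry) for entry in doc["assays"]]


def calibration_table() -> pd.DataFrame:
    """Published K-calibration data: five mixtures, replicate-mean copies/µL."""
    return pd.read_csv(
        resources.files("salmoquant") / "data" / "calibration_table.csv"
    )


def verification_table() -> pd.DataFrame:
    """Published verification mixtures (20–80%) with ddPCR and qPCR results."""
    return pd.read_csv(
        resources.files("salmoquant") / "data" / "verification_table.csv"
    )


def sensitivity_table() -> pd.DataFrame:
    """Published low-fraction series with detection rates and deviations.

    Deviations are signed; the 0.05% level (nothing detected) is −100%.
    """
    return pd.read_csv(
        resources.files("salmoquant") / "data" / "sensitivity_table.csv"
    )


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def synthetic_templates(seed: int = 7, flank: int = 80) -> list[SeqRecord]:
    """Deterministic synthetic templates, one per bundled assay.

    Each template is random sequence with the assay's forward-primer site,
    probe site, and reverse-primer binding site (as revcomp on the plus
    strand) planted so the product length equals ``expected_amplicon_bp``.
    Record ids carry a ``synthetic:`` prefix to make their nature explicit.
    """
    rng = np.random.default_rng(seed)
    records = []
    for assay in load_assays():
        length = assay.expected_amplicon_bp
        insert_len = length - len(assay.fwd_primer) - len(assay.rev_primer)
        if insert_len < len(assay.probe):
            raise ValueError("amplicon too short to hold the probe")
        pad = insert_len - len(assay.probe)
        left = pad // 2
        insert = (
            _random_bases(rng, left) + assay.probe + _random_bases(rng, pad - left)
        )
        product = assay.fwd_primer + insert + reverse_complement(assay.rev_primer)
        seq = _random_bases(rng, flank) + product + _random_bases(rng, flank)
        records.append(
            SeqRecord(
                Seq(seq),
                id=f"synthetic:{assay.accession}",
                description=f"synthetic template carrying the {assay.species_label} "
                f"myoglobin assay sites ({length} bp product)",
            )
        )
    return records
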