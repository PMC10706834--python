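"""Duplex TaqMan assay definitions and in-silico PCR.

An :class:`Assay` bundles the species-specific primer/probe set targeting the
single-copy nuclear myoglobin (MB) gene, the reporter dye it is read on, and
the GenBank accession of the targeted transcript. :func:`find_amplicons`
predicts plus-strand PCR products on a supplied template by Hamming-distance
primer matching (no indels; the 3'-terminal base of each primer must match
exactly, since a mismatched 3' end blocks polymerase extension), and
:func:`specificity_matrix` summarises which assay amplifies which template —
the computational analogue of a wet-lab cross-reactivity panel.

This mismatch model is an approximation of hybridisation-based specificity:
it knows nothing about melting temperature or secondary structure, so a
negative prediction here is necessary but not sufficient for wet-lab
specificity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement
from Bio.SeqRecord import SeqRecord

from .errors import InputError

# Expansion set for each IUPAC code, e.g. "R" -> {"A", "G"}.
_IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
_TEMPLATE_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class Assay:
    """One species-specific primer/probe set of a duplex ddPCR panel."""

    species_label: str
    gene: str
    accession: str
    fwd_primer: str
    rev_primer: str
    probe: str
    reporter_dye: str
    expected_amplicon_bp: int | None = None

    def __post_init__(self) -> None:
        for name in ("fwd_primer", "rev_primer", "probe"):
            seq = getattr(self, name)
            if not seq:
                raise InputError(f"{name} must be non-empty")
            bad = set(seq.upper()) - set(_IUPAC_SETS)
            if bad:
                raise InputError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
            object.__setattr__(self, name, seq.upper())
        if self.fwd_primer == self.rev_primer:
            raise InputError("forward and reverse primers must differ")
        if self.expected_amplicon_bp is not None and self.expected_amplicon_bp <= 0:
            raise InputError("expected_amplicon_bp must be positive")


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted plus-strand PCR product.

    ``start`` is the 0-based position of the forward primer's 5' end;
    ``end`` is one past the reverse primer's 5' end on the plus strand,
    so ``length_bp == end - start`` is the product length.
    """

    template_id: str
    start: int
    end: int
    length_bp: int
    mismatches_fwd: int
    mismatches_rev: int
    probe_present: bool


def _clean_template(template_id: str, seq: str) -> str:
    if not seq:
        raise InputError(f"template {template_id!r} is empty")
    seq = seq.upper().replace("U", "T")
    if not _TEMPLATE_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise InputError(f"template {template_id!r} has invalid characters: {bad}")
    return seq


def _as_id_seq(template) -> tuple[str, str]:
    """Accept a SeqRecord or an (id, sequence) pair."""
    if isinstance(template, SeqRecord):
        return template.id, str(template.seq)
    tid, seq = template
    return str(tid), str(seq)


def _mismatches(primer: str, window: str, max_allowed: int) -> int | None:
    """Hamming mismatches of an IUPAC primer against an ACGTN window.

    N in the template matches nothing. Returns None once the count exceeds
    ``max_allowed`` (early exit).
    """
    count = 0
    for p, t in zip(primer, window):
        if t == "N" or t not in _IUPAC_SETS[p]:
            count += 1
            if count > max_allowed:
                return None
    return count


def _site_matches(primer: str, seq: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where primer binds with an exact 3' base.

    ``primer`` is given 5'->3' as it lies on the plus strand, so its
    3'-terminal base is the last character of the window.
    """
    n, k = len(seq), len(primer)
    out = []
    for i in range(n - k + 1):
        window = seq[i : i + k]
        # exact-match requirement at the extension (3') end
        if window[-1] == "N" or window[-1] not in _IUPAC_SETS[primer[-1]]:
            continue
        mm = _mismatches(primer, window, max_mismatches)
        if mm is not None:
            out.append((i, mm))
    return out


def _probe_in(product: str, probe: str, max_mismatches: int) -> bool:
    for oriented in (probe, reverse_complement(probe)):
        k = len(oriented)
        for i in range(len(product) - k + 1):
            if _mismatches(oriented, product[i : i + k], max_mismatches) is not None:
                return True
    return False


def find_amplicons(
    template,
    assay: Assay,
    max_mismatches: int = 2,
    max_len: int = 2000,
    check_probe: bool = True,
) -> list[AmpliconHit]:
    """Predict plus-strand PCR products of ``assay`` on ``template``.

    A product requires the forward primer on the plus strand and the reverse
    complement of the reverse primer downstream, each within
    ``max_mismatches`` Hamming mismatches and with an exactly matching
    3'-terminal base. ``probe_present`` records whether the probe (either
    orientation) occurs inside the product; with ``check_probe=False`` it is
    reported as False without searching. Hits are sorted by start position.
    """
    template_id, seq = _as_id_seq(template)
    seq = _clean_template(template_id, seq)
    min_len = len(assay.fwd_primer) + len(assay.rev_primer)
    if len(seq) < min_len:
        raise InputError(
            f"template {template_id!r} shorter than combined primer length"
        )

    fwd_sites = _site_matches(assay.fwd_primer, seq, max_mismatches)
    # On the plus strand the reverse-primer site reads as revcomp(rev);
    # the primer's 3' end maps to the FIRST base of that window.
    rev_rc = reverse_complement(assay.rev_primer)
    rev_sites = []
    n, k = len(seq), len(rev_rc)
    for j in range(n - k + 1):
        window = seq[j : j + k]
        # 3' base of the reverse primer is complementary to window[0]
        if window[0] == "N" or window[0] not in _IUPAC_SETS[rev_rc[0]]:
            continue
        mm = _mismatches(rev_rc, window, max_mismatches)
        if mm is not None:
            rev_sites.append((j, mm))

    hits = []
    for i, mm_f in fwd_sites:
        for j, mm_r in rev_sites:
            end = j + k
            length = end - i
            if length < min_len or length > max_len:
                continue
            product = seq[i:end]
            probe_present = check_probe and _probe_in(
                product, assay.probe, max_mismatches
            )
            hits.append(
                AmpliconHit(
                    template_id=template_id,
                    start=i,
                    end=end,
                    length_bp=length,
                    mismatches_fwd=mm_f,
                    mismatches_rev=mm_r,
                    probe_present=probe_present,
                )
            )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def specificity_matrix(
    assays: Sequence[Assay],
    templates: Iterable,
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Assay x template cross-reactivity table.

    A cell is True iff the assay yields at least one amplicon on the template
    with the probe present — the in-silico counterpart of a positive droplet
    cluster in a specificity panel.
    """
    templates = list(templates)
    if not assays or not templates:
        raise InputError("assays and templates must be non-empty")
    ids = [_as_id_seq(t)[0] for t in templates]
    data = {}
    for tid, template in zip(ids, templates):
        col = []
        for assay in assays:
            hits = find_amplicons(template, assay, max_mismatches=max_mismatches)
            col.append(any(h.probe_present for h in hits))
        data[tid] = col
    return pd.DataFrame(data, index=[a.species_label for a in assays])
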