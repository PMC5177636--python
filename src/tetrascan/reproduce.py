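"""Reproduction of the published five-clone BAC insert analysis.

The five insert sequences are public GenBank records (see
``ACCESSIONS``); they are not redistributed here. Download them once
with ``scripts/fetch_accessions.py`` (network required) into a
directory, then :func:`clone_statistics` recomputes, per clone, the
insert length, G+C percentage and the mean/SD internal tetranucleotide
window correlation under both strand-handling modes, and
:func:`coding_correlation` the cross-clone Pearson R between published
coding percentages and the computed mean correlations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .annotation import pearson_pvalue
from .io import gc_content, read_fasta
from .tetra import WindowSpec, correlation_matrix

#: GenBank accession -> clone name for the five BAC inserts.
ACCESSIONS = {
    "KT342854": "4C6",
    "KT342855": "5E7",
    "KT342856": "5G4",
    "KT342857": "5G12",
    "KT342858": "5H7",
}

#: Published per-clone coding-region percentages (annotation-derived
#: inputs; gene prediction itself is outside this package's scope).
PUBLISHED_CODING_PERCENT = {
    "4C6": 54.4,
    "5E7": 75.6,
    "5G4": 44.4,
    "5G12": 58.0,
    "5H7": 65.0,
}


@dataclass
class CloneStats:
    clone: str
    accession: str
    length: int
    gc_percent: float
    mean_r: dict  # extension mode -> mean r
    sd_r: dict


def _find_fasta(directory: str, accession: str) -> str | None:
    for ext in (".fasta", ".fa", ".fna"):
        p = os.path.join(directory, accession + ext)
        if os.path.exists(p):
            return p
    return None


def clone_statistics(directory: str) -> list[CloneStats]:
    """Compute sequence-derived statistics for all five downloaded clones.

    Raises ``FileNotFoundError`` with download instructions when any
    accession FASTA is missing from ``directory``.
    """
    stats: list[CloneStats] = []
    for accession, clone in ACCESSIONS.items():
        path = _find_fasta(directory, accession)
        if path is None:
            raise FileNotFoundError(
                f"{accession}.fasta not found in {directory!r}; run "
                "'python scripts/fetch_accessions.py --out <dir>' (network required)"
            )
        record = read_fasta(path)[0]
        mean_r, sd_r = {}, {}
        for mode in ("per_window_rc", "whole_sequence_rc"):
            m = correlation_matrix(record, WindowSpec(extension_mode=mode))
            mean_r[mode], sd_r[mode] = m.mean_r, m.sd_r
        stats.append(
            CloneStats(
                clone=clone,
                accession=accession,
                length=len(record.seq),
                gc_percent=gc_content(record.seq),
                mean_r=mean_r,
                sd_r=sd_r,
            )
        )
    return stats


def coding_correlation(stats: list[CloneStats], mode: str = "per_window_rc") -> tuple[float, float]:
    """Pearson R (and p) between published coding % and computed mean r."""
    import numpy as np

    xs = np.array([PUBLISHED_CODING_PERCENT[s.clone] for s in stats])
    ys = np.array([s.mean_r[mode] for s in stats])
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, pearson_pvalue(r, len(stats))
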