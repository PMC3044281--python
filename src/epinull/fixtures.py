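"""Deterministic worked-example fixtures.

The canonical two-SNP toy example (1000 cases, 1000 controls) whose 3x3
case/control genotype tables collapse to the 2x2 table
(low: 399/443, high: 601/557) with Pearson chi-square 3.971.  The expansion
into a 2000-sample dataset makes every end-to-end stage runnable on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import GenotypeDataset

__all__ = ["Table1Fixture", "table1", "table1_dataset"]

_CASE = np.array([[179, 119, 18], [315, 173, 26], [101, 59, 10]], dtype=np.int64)
_CONTROL = np.array([[199, 126, 15], [306, 164, 17], [118, 49, 6]], dtype=np.int64)


@dataclass(frozen=True)
class Table1Fixture:
    """3x3 case and control genotype counts of the worked example."""

    case: np.ndarray
    control: np.ndarray


def table1() -> Table1Fixture:
    """The printed 3x3 case/control tables (1000 samples per class)."""
    return Table1Fixture(_CASE.copy(), _CONTROL.copy())


def table1_dataset() -> GenotypeDataset:
    """2000-sample, 2-SNP dataset whose tabulation reproduces :func:`table1`.

    Samples are emitted cell-major (lexicographic genotype order) and, within
    each cell, cases before controls; byte-identical across runs.
    """
    fix = table1()
    rows = []
    phen = []
    for g1 in range(3):
        for g2 in range(3):
            for cls, tab in ((1, fix.case), (0, fix.control)):
                count = int(tab[g1, g2])
                rows.append(np.tile([g1, g2], (count, 1)))
                phen.append(np.full(count, cls))
    geno = np.concatenate(rows).astype(np.int8)
    return GenotypeDataset(geno, np.concatenate(phen), ["SNP_A", "SNP_B"])
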