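"""Preprocessing for raw concentration tables.

GC-MS metabolite concentrations span several orders of magnitude (roughly
1e-4 to 10), with exact zeros recorded for metabolites below the detection
limit.  Two rules make the table usable for distance-based analysis:

1. every exact zero is replaced with a small positive fill value one order
   of magnitude below the detection floor (default 1e-5), so that
   below-detection metabolites are retained as potential biomarkers;
2. the table is log-transformed (base 10 by default), mapping the dynamic
   range [1e-4, 10] to [-4, 1] and fills to -5.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .io import MetaboliteTable

__all__ = ["replace_zeros", "log_transform", "preprocess"]


def replace_zeros(table: MetaboliteTable, zero_fill: float = 1e-5) -> MetaboliteTable:
    """Replace exact-zero concentrations with ``zero_fill``.

    Only exact zeros are touched: small positive values below the fill are
    genuine measurements and pass through unchanged.  Idempotent; returns a
    new table.
    """
    if zero_fill <= 0:
        raise DomainError("zero_fill must be positive")
    if table.scale != "raw":
        raise DomainError("replace_zeros expects a raw-scale table")
    if np.any(table.values < 0):
        raise DomainError("negative concentration encountered")
    out = table.copy()
    out.values[out.values == 0.0] = zero_fill
    return out


def log_transform(table: MetaboliteTable, log_base: float = 10.0) -> MetaboliteTable:
    """Entrywise logarithm; flips the scale flag to ``log``.

    All entries must be strictly positive — run :func:`replace_zeros` first.
    """
    if log_base <= 0 or log_base == 1:
        raise DomainError("log_base must be positive and != 1")
    if table.scale != "raw":
        raise DomainError("log_transform expects a raw-scale table")
    if np.any(table.values <= 0):
        raise DomainError(
            "zero or negative entry present; run replace_zeros before log_transform"
        )
    out = table.copy()
    out.values = np.log(out.values) / np.log(log_base)
    out.scale = "log"
    return out


def preprocess(
    table: MetaboliteTable, zero_fill: float = 1e-5, log_base: float = 10.0
) -> MetaboliteTable:
    """Zero replacement followed by log transformation."""
    return log_transform(replace_zeros(table, zero_fill), log_base)
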