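"""Synthetic clove-bud-like metabolite tables with known ground truth.

The generator emulates the structure of a GC-MS metabolite study of plant
material sampled from several geographic origins: each origin contributes a
few independent samples ("regions"), each region is measured 6-8 times
("replicates" / independent analyses), and ~47 metabolites are quantified
per run with concentrations spanning 1e-4 to 10.

Generative model (all in log10 space):

* a base abundance profile, uniform over ``base_range``;
* per origin, a random subset of metabolites (fraction ``shift_fraction``)
  is shifted by +/- ``origin_sep`` — the between-origin signal;
* per region, a Gaussian offset vector (sd ``region_sd``);
* per replicate, i.i.d. Gaussian noise (sd ``replicate_sd``);
* optional contamination: selected replicates get an extra
  ``outlier_shift`` on a random half of the metabolites (a partial
  measurement error, like a mis-measured analysis batch);
* back on the concentration scale, values below ``detection_limit`` are
  censored to exact 0.

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from .io import MetaboliteTable

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "inject_outliers"]

_DEFAULT_ORIGINS = ["Manado", "ToliToli", "Bali", "Jawa"]


@dataclass
class SyntheticConfig:
    """Parameters of the generator; defaults mirror the emulated study design."""

    n_origins: int = 4
    regions_per_origin: int = 3
    replicates_per_region: int | list[int] = 8
    n_metabolites: int = 47
    origin_sep: float = 1.5       # delta: between-origin log10 shift
    region_sd: float = 0.2        # within-origin region offset sd
    replicate_sd: float = 0.3     # sigma: replicate noise sd
    base_range: tuple[float, float] = (-4.0, 1.0)
    detection_limit: float = 1e-4
    contamination_rate: float = 0.0   # pi: per-replicate outlier probability
    outlier_shift: float = 0.0        # Delta: contamination shift, log10 units
    shift_fraction: float = 0.3       # fraction of metabolites shifted per origin
    seed: int = 0

    def validate(self) -> None:
        if self.n_origins < 1 or self.regions_per_origin < 1:
            raise DomainError("need at least one origin and one region per origin")
        if self.n_metabolites < 1:
            raise DomainError("need at least one metabolite")
        if self.region_sd < 0 or self.replicate_sd < 0:
            raise DomainError("noise levels must be non-negative")
        if self.region_sd > 0 and not self.origin_sep > self.region_sd:
            raise DomainError(
                "origin_sep must exceed region_sd for identifiable structure"
            )
        if self.detection_limit <= 0:
            raise DomainError("detection_limit must be positive")
        if not 0 <= self.contamination_rate < 1:
            raise DomainError("contamination_rate must be in [0, 1)")
        if not 0 < self.shift_fraction <= 1:
            raise DomainError("shift_fraction must be in (0, 1]")

    def replicate_counts(self) -> list[int]:
        n_regions = self.n_origins * self.regions_per_origin
        if isinstance(self.replicates_per_region, int):
            counts = [self.replicates_per_region] * n_regions
        else:
            counts = list(self.replicates_per_region)
            if len(counts) != n_regions:
                raise DomainError(
                    f"{len(counts)} replicate counts for {n_regions} regions"
                )
        if any(c < 1 for c in counts):
            raise DomainError("every region needs >= 1 replicate")
        return counts


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    origin_of_region: dict[str, str]
    contaminated: list[tuple[str, int]] = field(default_factory=list)
    origin_log_profiles: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _origin_names(n: int) -> list[str]:
    if n <= len(_DEFAULT_ORIGINS):
        return _DEFAULT_ORIGINS[:n]
    return _DEFAULT_ORIGINS + [f"Origin{i}" for i in range(len(_DEFAULT_ORIGINS) + 1, n + 1)]


def generate(config: SyntheticConfig) -> tuple[MetaboliteTable, GroundTruth]:
    """Draw one table (raw scale, censored) plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.n_metabolites
    lo, hi = config.base_range
    base = rng.uniform(lo, hi, size=d)

    origins = _origin_names(config.n_origins)
    profiles: dict[str, np.ndarray] = {}
    for origin in origins:
        mask = rng.random(d) < config.shift_fraction
        signs = rng.choice([-1.0, 1.0], size=d)
        profiles[origin] = base + mask * signs * config.origin_sep

    counts = config.replicate_counts()
    columns: list[np.ndarray] = []
    meta_rows: list[tuple[str, str, int]] = []
    origin_of_region: dict[str, str] = {}
    contaminated: list[tuple[str, int]] = []
    ri = 0
    for origin in origins:
        for r in range(1, config.regions_per_origin + 1):
            region = f"{origin[0]}{r}"
            origin_of_region[region] = origin
            offset = rng.normal(0.0, config.region_sd, size=d)
            for rep in range(1, counts[ri] + 1):
                col = profiles[origin] + offset + rng.normal(
                    0.0, config.replicate_sd, size=d
                )
                if config.contamination_rate > 0 and rng.random() < config.contamination_rate:
                    idx = rng.choice(d, size=d // 2, replace=False)
                    col = col.copy()
                    col[idx] += config.outlier_shift
                    contaminated.append((region, rep))
                columns.append(col)
                meta_rows.append((origin, region, rep))
            ri += 1

    log_values = np.column_stack(columns)
    conc = 10.0**log_values
    conc[conc < config.detection_limit] = 0.0

    table = MetaboliteTable(
        values=conc,
        metabolite_ids=[f"m{i + 1}" for i in range(d)],
        sample_meta=pd.DataFrame(meta_rows, columns=["origin", "region", "replicate"]),
        scale="raw",
    )
    truth = GroundTruth(
        origin_of_region=origin_of_region,
        contaminated=contaminated,
        origin_log_profiles={o: list(p) for o, p in profiles.items()},
    )
    return table, truth


def inject_outliers(
    table: MetaboliteTable,
    pairs: list[tuple[str, int]],
    shift: float,
    seed: int = 0,
    truth: GroundTruth | None = None,
    detection_limit: float = 1e-4,
) -> tuple[MetaboliteTable, GroundTruth]:
    """Contaminate named (region, replicate) columns of a raw table.

    The shift is ``shift`` log10 units applied multiplicatively to a random
    half of the metabolites of each named column; censored zeros stay zero,
    and shifted values falling below the detection limit are re-censored.
    """
    if table.scale != "raw":
        raise DomainError("inject_outliers expects a raw-scale table")
    rng = np.random.default_rng(seed)
    out = table.copy()
    d = out.n_metabolites
    meta = out.sample_meta
    new_contaminated: list[tuple[str, int]] = []
    for region, rep in pairs:
        hit = np.flatnonzero((meta["region"] == region) & (meta["replicate"] == rep))
        if len(hit) != 1:
            raise DomainError(f"no sample column for (region={region!r}, replicate={rep})")
        j = int(hit[0])
        idx = rng.choice(d, size=d // 2, replace=False)
        if shift != 0.0:
            out.values[idx, j] *= 10.0**shift
            out.values[out.values[:, j] < detection_limit, j] = 0.0
        new_contaminated.append((region, rep))
    if truth is None:
        truth = GroundTruth(
            origin_of_region={
                r.region: r.origin for r in meta.drop_duplicates("region").itertuples()
            }
        )
    if shift != 0.0:
        truth = GroundTruth(
            origin_of_region=dict(truth.origin_of_region),
            contaminated=list(truth.contaminated) + new_contaminated,
            origin_log_profiles=dict(truth.origin_log_profiles),
        )
    return out, truth
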