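"""Synthetic-data generators with the statistical structure the analysis assumes.

Three generators cover every analysis input:

* Bernoulli detection records with additive site/method structure on the
  logit scale (what the detection GLM expects);
* multi-site community incidence/read matrices whose within-site similarity
  exceeds between-site similarity, with a turnover dial controlling beta
  diversity (and hence the fitted accumulation-model ``z``);
* ASV hit tables exercising every consensus-taxonomy rule, with ground-truth
  assignments embedded so the consensus procedure can be checked round-trip.

Every generator is deterministic under a fixed integer seed.  Each draws
from named substreams (sites, species, reads, ...) so that, e.g., enlarging
the species pool does not perturb the site-level draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .community import ASVHit, ASVRecord, ConsensusAssignment, PlausibleList

__all__ = [
    "DetectionSimSpec",
    "CommunitySimSpec",
    "ASVSimSpec",
    "simulate_detection",
    "simulate_community",
    "simulate_asv_table",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """A named substream: one generator per (seed, purpose) pair."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Detection records


@dataclass(frozen=True)
class DetectionSimSpec:
    """Logit-additive Bernoulli detection design.

    ``site_effects`` are logit-scale intercepts per site; ``method_effects``
    are logit-scale offsets per method.  ``samples_per_cell`` gives how many
    samples each site x method cell receives (an int, or a mapping keyed by
    (site, method)).
    """

    site_effects: Mapping[str, float]
    method_effects: Mapping[str, float]
    samples_per_cell: int | Mapping[tuple[str, str], int] = 20
    seed: int = 0

    def cell_size(self, site: str, method: str) -> int:
        if isinstance(self.samples_per_cell, int):
            size = self.samples_per_cell
        else:
            size = self.samples_per_cell[(site, method)]
        if size < 1:
            raise ValueError(f"samples per cell must be >= 1, got {size}")
        return size


def simulate_detection(spec: DetectionSimSpec) -> pd.DataFrame:
    """Independent Bernoulli detections, p = inverse_logit(site + method effect)."""
    rng = _rng(spec.seed, "detection")
    rows = []
    for site in spec.site_effects:
        for method in spec.method_effects:
            p = expit(spec.site_effects[site] + spec.method_effects[method])
            size = spec.cell_size(site, method)
            draws = rng.random(size) < p
            for i, hit in enumerate(draws):
                rows.append((site, method, f"{site}-{method}-{i:04d}", int(hit)))
    return pd.DataFrame(rows, columns=["site_id", "method", "sample_id", "detected"])


# ---------------------------------------------------------------------------
# Community matrices


@dataclass(frozen=True)
class CommunitySimSpec:
    """Occupancy/detection community generator with a beta-diversity dial.

    Each of ``pool`` regional species occupies sites with probability
    ``occupancy``; ``turnover`` in [0, 1] interpolates between perfectly
    correlated occupancy across sites (0: a species is everywhere or
    nowhere, no beta diversity) and independent per-site occupancy (1:
    maximal turnover).  At an occupied site each sample detects the species
    with probability ``detection`` — this is what makes samples from the
    same site more similar than samples from different sites.  Optional
    read counts are drawn from a heavy-tailed log-normal law.
    """

    pool: int = 30
    occupancy: float = 0.6
    detection: float = 0.7
    turnover: float = 0.3
    k: int = 8
    n: int = 2
    reads: bool = False
    read_mean_log: float = 5.0
    read_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("occupancy", "detection", "turnover"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.pool < 1:
            raise ValueError(f"species pool must be >= 1, got {self.pool}")


def simulate_community(spec: CommunitySimSpec) -> pd.DataFrame:
    """Sample x species matrix (site_id, sample_id, then species columns)."""
    rng_sites = _rng(spec.seed, "sites")
    rng_species = _rng(spec.seed, "species")
    rng_reads = _rng(spec.seed, "reads")

    species = [f"sp{j:03d}" for j in range(spec.pool)]
    # correlated occupancy: each species has one shared uniform; each site
    # either reuses it (prob 1 - turnover) or draws a fresh one
    shared = rng_species.random(spec.pool)
    fresh = rng_sites.random((spec.k, spec.pool))
    reuse = rng_sites.random((spec.k, spec.pool)) >= spec.turnover
    u = np.where(reuse, shared[None, :], fresh)
    occupied = u < spec.occupancy  # (k, pool)

    detected = (
        rng_species.random((spec.k, spec.n, spec.pool)) < spec.detection
    ) & occupied[:, None, :]

    if spec.reads:
        counts = np.round(
            np.exp(rng_reads.normal(spec.read_mean_log, spec.read_sigma,
                                    size=detected.shape))
        ).astype(np.int64)
        values = np.where(detected, np.maximum(counts, 1), 0)
    else:
        values = detected.astype(np.int64)

    rows = []
    for i in range(spec.k):
        for j in range(spec.n):
            rows.append(
                {"site_id": f"site{i:02d}", "sample_id": f"site{i:02d}-s{j}",
                 **dict(zip(species, values[i, j]))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ASV hit tables


@dataclass(frozen=True)
class ASVSimSpec:
    """Generator for ASV hit tables spanning every consensus-taxonomy rule.

    The generated set always contains at least one ASV of each kind:
    sub-threshold reads (including exactly 7, the filter boundary), a single
    plausible species hit, an implausible hit needing reassignment, a
    multi-candidate tie needing a lowest-common-taxon consensus, and an
    exogenous-flagged taxon.  Beyond those, kinds are drawn with the given
    fractions.  Ground-truth assignments are attached to every ASV.
    """

    n_asvs: int = 30
    implausible_fraction: float = 0.2
    tie_fraction: float = 0.2
    exogenous_fraction: float = 0.1
    subthreshold_fraction: float = 0.1
    read_mean_log: float = 5.0
    read_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("implausible_fraction", "tie_fraction",
                     "exogenous_fraction", "subthreshold_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        total = (self.implausible_fraction + self.tie_fraction
                 + self.exogenous_fraction + self.subthreshold_fraction)
        if total > 1.0:
            raise ValueError(f"kind fractions sum to {total} > 1")
        if self.n_asvs < 5:
            raise ValueError("need at least 5 ASVs to span every rule")


def _synthetic_taxonomy() -> pd.DataFrame:
    """A small synthetic fish-like taxonomy exercising every consensus rule.

    Genus Gena holds a plausible/implausible species pair (reassignment
    target is unique); genus Genb holds two plausible congeners (ties
    resolve to the genus); Gend is marine-flagged (exogenous); Gene is
    entirely implausible with no relatives on the list (unassignable).
    """
    rows = [
        # taxon, order, family, genus, species, plausible, habitat
        ("Gena alpha", "Ord1", "Fam1", "Gena", True, "estuarine"),
        ("Gena ghost", "Ord1", "Fam1", "Gena", False, "estuarine"),
        ("Genb beta", "Ord1", "Fam2", "Genb", True, "estuarine"),
        ("Genb gamma", "Ord1", "Fam2", "Genb", True, "estuarine"),
        ("Genc delta", "Ord2", "Fam3", "Genc", True, "freshwater"),
        ("Gend epsilon", "Ord2", "Fam4", "Gend", True, "marine"),
        ("Gene zeta", "Ord3", "Fam5", "Gene", False, "estuarine"),
    ]
    return pd.DataFrame(
        [
            dict(taxon=t, **{"class": "Actinopteri"}, order=o, family=f, genus=g,
                 species=t, plausible=p, habitat=h)
            for t, o, f, g, p, h in rows
        ]
    )


def simulate_asv_table(
    spec: ASVSimSpec,
) -> tuple[list[ASVRecord], PlausibleList, dict[str, ConsensusAssignment | None]]:
    """Generate (ASV records, plausible list, ground truth).

    Ground truth maps each asv_id to its expected consensus assignment, or
    to None for ASVs that the read filter should remove.
    """
    plausible = PlausibleList(_synthetic_taxonomy())
    rng_kinds = _rng(spec.seed, "asv-kinds")
    rng_reads = _rng(spec.seed, "asv-reads")
    rng_ident = _rng(spec.seed, "asv-identity")

    kinds = ["subthreshold", "single", "implausible", "tie", "exogenous"]
    probs = [
        spec.subthreshold_fraction,
        1.0 - (spec.subthreshold_fraction + spec.implausible_fraction
               + spec.tie_fraction + spec.exogenous_fraction),
        spec.implausible_fraction,
        spec.tie_fraction,
        spec.exogenous_fraction,
    ]
    # always emit the filter-boundary ASV, plus one of each kind that has
    # positive probability; the rest are drawn with the given fractions
    mandatory = ["subthreshold"] + [
        kind for kind, p in zip(kinds, probs) if kind != "subthreshold" and p > 0
    ]
    n_drawn = spec.n_asvs - len(mandatory)
    if n_drawn < 0:
        raise ValueError("n_asvs too small for the requested kind mix")
    assigned = mandatory + list(rng_kinds.choice(kinds, size=n_drawn, p=probs))

    records: list[ASVRecord] = []
    truth: dict[str, ConsensusAssignment | None] = {}
    boundary_emitted = False
    for i, kind in enumerate(assigned):
        asv_id = f"ASV{i:04d}"
        reads = int(max(8, round(np.exp(rng_reads.normal(spec.read_mean_log, spec.read_sigma)))))
        top = float(np.round(rng_ident.uniform(95.0, 100.0), 1))
        low = float(np.round(top - rng_ident.uniform(1.0, 4.0), 1))
        if kind == "subthreshold":
            reads = 7 if not boundary_emitted else int(rng_reads.integers(0, 8))
            boundary_emitted = True
            hits = (ASVHit("Gena alpha", top),)
            expected = None
        elif kind == "single":
            hits = (ASVHit("Genc delta", top), ASVHit("Genb beta", low))
            expected = ConsensusAssignment(asv_id, "Genc delta", "species", reads=reads)
        elif kind == "implausible":
            # Gena ghost is off-list; its unique closest plausible relative
            # is the congener Gena alpha
            hits = (ASVHit("Gena ghost", top),)
            expected = ConsensusAssignment(
                asv_id, "Gena alpha", "species",
                reassigned_from=("Gena ghost",), reads=reads,
            )
        elif kind == "tie":
            hits = (ASVHit("Genb beta", top), ASVHit("Genb gamma", top),
                    ASVHit("Genc delta", low))
            expected = ConsensusAssignment(asv_id, "Genb", "genus", reads=reads)
        else:  # exogenous
            hits = (ASVHit("Gend epsilon", top),)
            expected = ConsensusAssignment(
                asv_id, "Gend epsilon", "species", exogenous=True, reads=reads
            )
        records.append(ASVRecord(asv_id=asv_id, total_reads=reads, hits=hits))
        truth[asv_id] = expected
    return records, plausible, truth
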