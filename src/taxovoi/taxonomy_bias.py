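"""Per-taxon relative representation of citizen-science observations.

A taxon's relative representation is

    R_x = n_x - n * s_x / s

where ``n_x`` is the number of observations for taxon x, ``n`` the total
observations over the analyzed taxa, ``s_x`` the number of accepted species
in taxon x, and ``s`` the total species over the analyzed taxa.  R_x > 0
means the taxon receives more observations than its species richness alone
would predict; R_x < 0 means it is under-represented.  Over a set of taxa
that partition the dataset the R_x sum to zero by construction.

Because R_x spans orders of magnitude in both directions, results are also
returned on an inverse-hyperbolic-sine scale, which is logarithmic in |R_x|
for large values yet linear (and sign-preserving) near zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .dwc_io import ObservationRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepresentationResult:
    taxon: str
    rank: str
    n_x: int
    s_x: int
    r_x: float
    r_x_asinh: float


def asinh_transform(value: float) -> float:
    """Inverse hyperbolic sine: sign-preserving, log-like display scale."""
    if not math.isfinite(value):
        raise ValueError(f"asinh_transform requires finite input, got {value}")
    return math.asinh(value)


def image_observation_tallies(observations: Iterable[ObservationRecord],
                              rank: str,
                              images_only: bool = True) -> dict[str, int]:
    """Count observations (not images) per taxon at ``rank``.

    With ``images_only`` set, only observations carrying at least one image
    reference are counted — the unit of interest when the downstream use is
    recognition-model training data.  Records whose taxonomy lacks the
    requested rank are excluded (and their number logged).
    """
    tallies: dict[str, int] = {}
    n_missing = 0
    for rec in observations:
        taxon = rec.taxonomy.get(rank)
        if not taxon:
            n_missing += 1
            continue
        if images_only and not rec.has_image:
            continue
        tallies[taxon] = tallies.get(taxon, 0) + 1
    if n_missing:
        logger.warning("excluded %d observation(s) lacking rank %r",
                       n_missing, rank)
    return tallies


def relative_representation(tallies: Mapping[str, int],
                            species_counts: Mapping[str, int],
                            rank: str = "order",
                            ) -> list[RepresentationResult]:
    """Compute R_x = n_x - n*s_x/s for every tallied taxon.

    The totals ``n`` and ``s`` are taken over exactly the taxa supplied in
    ``tallies``; the caller chooses the analysis universe (e.g. all classes,
    or a selected set of orders) explicitly.

    Returns results sorted by R_x descending (most over-represented first).

    Raises
    ------
    KeyError
        if a tallied taxon is missing from ``species_counts``.
    ValueError
        if a tallied taxon has zero accepted species.
    """
    missing = [t for t in tallies if t not in species_counts]
    if missing:
        raise KeyError(
            f"taxa missing from checklist: {', '.join(sorted(missing))}")
    zero = [t for t in tallies if species_counts[t] == 0]
    if zero:
        raise ValueError(
            f"taxa with zero accepted species: {', '.join(sorted(zero))}")

    n = sum(tallies.values())
    s = sum(species_counts[t] for t in tallies)
    if s <= 0:
        raise ValueError("total species count must be positive")

    results = []
    for taxon, n_x in tallies.items():
        s_x = species_counts[taxon]
        r_x = n_x - n * s_x / s
        results.append(RepresentationResult(
            taxon=taxon, rank=rank, n_x=n_x, s_x=s_x,
            r_x=r_x, r_x_asinh=asinh_transform(r_x)))
    results.sort(key=lambda r: (-r.r_x, r.taxon))
    return results
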