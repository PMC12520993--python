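"""MIT (Hsu) aggregate specificity score by brute-force off-target search.

The per-site penalty uses the published position-dependent mismatch weights:
for a site with mismatches at protospacer positions ``P`` (0-based, 5'->3'),

    penalty = 100 * prod_{p in P} (1 - W[p])
                  * 1 / (((19 - dbar) / 19) * 4 + 1)
                  * 1 / n^2

where ``dbar`` is the mean pairwise distance between mismatch positions and
``n = |P|`` (distance and multiplicity terms are 1 when n < 2).  The guide
score aggregates penalties over every enumerated off-target site:

    score = 100 * 100 / (100 + sum(penalties))

so a guide whose only genomic match is the on-target site scores 100, and a
single perfect duplicate (penalty 100) scores 50.
"""

from __future__ import annotations

import warnings
from itertools import combinations

from .variant_io import revcomp

#: Position-dependent mismatch weights, protospacer positions 1..20 (5'->3').
HSU_WEIGHTS = (
    0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
)


def site_penalty(mismatch_positions) -> float:
    """Hsu penalty of one off-target site given its mismatch positions."""
    positions = sorted(mismatch_positions)
    n = len(positions)
    term = 100.0
    for p in positions:
        term *= 1.0 - HSU_WEIGHTS[p]
    if n >= 2:
        pairs = list(combinations(positions, 2))
        dbar = sum(b - a for a, b in pairs) / len(pairs)
        term *= 1.0 / (((19.0 - dbar) / 19.0) * 4.0 + 1.0)
        term *= 1.0 / (n * n)
    return term


def _iter_ngg_sites(seq: str):
    """Yield (site20, mismatch-comparable) 20-mers 5' of every NGG in ``seq``
    and its reverse complement."""
    for s in (seq, revcomp(seq)):
        for i in range(20, len(s) - 2):
            if s[i + 1 : i + 3] == "GG":
                yield s[i - 20 : i]


def mit_specificity(
    protospacer, reference_seqs: dict, max_mismatches: int = 4
) -> float:
    """Aggregate MIT specificity of a protospacer against a reference set.

    ``protospacer`` is a :class:`~pegsensor.design.Protospacer` or a plain
    20-nt string; ``reference_seqs`` maps names to sequences (a desk-scale
    surrogate genome).  All NGG sites with at most ``max_mismatches``
    mismatches are penalized; one exact occurrence is treated as the
    on-target site and excluded.  A missing on-target site produces a
    warning and the score is computed over the sites found.
    """
    seq20 = getattr(protospacer, "seq20", protospacer).upper()
    if len(seq20) != 20:
        raise ValueError("protospacer must be 20 nt")
    penalties = []
    exact_seen = 0
    for site in _iter_ngg_sites_all(reference_seqs):
        mismatches = [p for p in range(20) if site[p] != seq20[p]]
        if len(mismatches) > max_mismatches:
            continue
        if not mismatches and exact_seen == 0:
            exact_seen = 1  # the on-target site itself
            continue
        penalties.append(site_penalty(mismatches))
    if not exact_seen:
        warnings.warn(
            "on-target site not found in reference set; score computed over "
            "found sites only",
            stacklevel=2,
        )
    return 100.0 * 100.0 / (100.0 + sum(penalties))


def _iter_ngg_sites_all(reference_seqs: dict):
    for seq in reference_seqs.values():
        yield from _iter_ngg_sites(seq.upper())
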