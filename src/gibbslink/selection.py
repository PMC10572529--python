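"""Per-sample target-edge selection and cohort aggregation.

For each sample the method picks one interaction to inhibit: the *anchor* is
the node with the most negative Gibbs contribution; the *partner* is the
anchor's covered neighbor with the highest normalized expression.  The
anchor–partner pair is an existing network edge by construction — the link
to block, leaving both proteins' other interactions untouched.  Across a
cohort, per-sample pairs are counted into a Pareto-ranked table.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .expression import ExpressionProfile
from .gibbs import GibbsScores, gibbs_energy
from .network_io import PPINetwork

logger = logging.getLogger(__name__)


class NoTargetError(ValueError):
    """Raised when no scored node has a covered neighbor (sample skipped)."""


@dataclass
class TargetPair:
    """The selected interaction for one sample: (anchor, partner) edge."""

    sample_id: str
    anchor: str
    partner: str
    anchor_G: float  # <= 0
    partner_c: float  # in [0, 1]


@dataclass
class CohortTargetTable:
    """Pareto-ranked counts of target pairs across a cohort.

    ``rows`` columns: anchor, partner, patient_count — descending count,
    ties in lexicographic (anchor, partner) order.  Counts over rows plus
    ``skipped`` sum to ``total_samples``.
    """

    rows: pd.DataFrame
    total_samples: int
    skipped: int = 0
    skipped_samples: list[str] = field(default_factory=list)


def select_anchor(scores: GibbsScores) -> str:
    """Return the node with the most negative Gibbs score.

    Ties break to the lexicographically smallest node identifier.
    """
    if not scores.G:
        raise ValueError(f"sample {scores.sample_id!r}: no scored nodes")
    return min(scores.G, key=lambda n: (scores.G[n], n))


def select_partner(network: PPINetwork, anchor: str, profile: ExpressionProfile) -> str:
    """Return the anchor's covered neighbor with maximal expression.

    Ties break lexicographically.  Neighbors without expression data are
    ineligible.
    """
    covered = [j for j in network.graph.neighbors(anchor) if j in profile.c]
    if not covered:
        raise NoTargetError(
            f"sample {profile.sample_id!r}: anchor {anchor!r} has no covered neighbor"
        )
    return min(covered, key=lambda j: (-profile.c[j], j))


def select_target(network: PPINetwork, profile: ExpressionProfile) -> TargetPair:
    """Select the target edge for one sample.

    Composes Gibbs scoring, anchor selection and partner selection.  If the
    most negative node has no covered neighbor (an isolated corner of the
    data), selection falls back to the next node in ascending-G order; only
    when no scored node has a covered neighbor is the sample skipped, via
    :class:`NoTargetError`.
    """
    scores = gibbs_energy(network, profile)
    ranked = sorted(scores.G, key=lambda n: (scores.G[n], n))
    for anchor in ranked:
        covered = [j for j in network.graph.neighbors(anchor) if j in profile.c]
        if covered:
            if anchor != ranked[0]:
                logger.info(
                    "select_target(%s): anchor fell back from %s to %s (no covered neighbor)",
                    profile.sample_id, ranked[0], anchor,
                )
            partner = min(covered, key=lambda j: (-profile.c[j], j))
            return TargetPair(
                sample_id=profile.sample_id,
                anchor=anchor,
                partner=partner,
                anchor_G=scores.G[anchor],
                partner_c=profile.c[partner],
            )
    raise NoTargetError(
        f"sample {profile.sample_id!r}: no scored node has a covered neighbor"
    )


def aggregate_cohort(
    pairs: list[TargetPair],
    total_samples: int,
    skipped_samples: list[str] | None = None,
    ordered: bool = True,
) -> CohortTargetTable:
    """Count target pairs across a cohort into a Pareto table.

    By default pairs are keyed ordered (anchor first), since the two roles
    are asymmetric — one is energy-selected, the other expression-selected.
    With ``ordered=False`` the edge is keyed as an unordered pair (the
    lexicographically smaller endpoint is written first).
    """
    skipped_samples = list(skipped_samples or [])
    counts: Counter[tuple[str, str]] = Counter()
    for p in pairs:
        key = (p.anchor, p.partner) if ordered else tuple(sorted((p.anchor, p.partner)))
        counts[key] += 1
    rows = pd.DataFrame(
        [(a, b, n) for (a, b), n in counts.items()],
        columns=["anchor", "partner", "patient_count"],
    )
    rows = rows.sort_values(
        ["patient_count", "anchor", "partner"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return CohortTargetTable(
        rows=rows,
        total_samples=total_samples,
        skipped=len(skipped_samples),
        skipped_samples=skipped_samples,
    )


def targets_frame(pairs: list[TargetPair]) -> pd.DataFrame:
    """Per-sample target table: sample_id, anchor, partner, anchor_G, partner_c."""
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "anchor": p.anchor,
                "partner": p.partner,
                "anchor_G": p.anchor_G,
                "partner_c": p.partner_c,
            }
            for p in pairs
        ],
        columns=["sample_id", "anchor", "partner", "anchor_G", "partner_c"],
    )


def pareto_chart(table: CohortTargetTable, path: str, top: int = 20) -> None:
    """Write a Pareto bar chart of the most frequent target pairs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = table.rows.head(top)
    labels = [f"{a}-{b}" for a, b in zip(rows["anchor"], rows["partner"])]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(labels) + 1), 4))
    ax.bar(range(len(labels)), rows["patient_count"], color="tab:blue")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("patients")
    ax.set_title(f"Target pairs across {table.total_samples} samples")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
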