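"""Per-node Gibbs free-energy contributions.

Each covered node i receives

    G_i = c_i * ln( c_i / (c_i + sum_{j in N(i), j covered} c_j) )

where c is the sample's normalized concentration surrogate and N(i) the
node's network neighbors.  The denominator is the closed-neighborhood
concentration sum — it includes c_i itself — so the log argument never
exceeds 1 and every score is <= 0.  The more negative G_i, the larger the
node's contribution to the stability of the interaction network for this
sample.  G is a dimensionless score, not a physical energy; no temperature
or units are attached.

Conventions at the boundary, by continuity of x ln x:
c_i = 0 => G_i = 0; a node whose whole covered closed neighborhood is zero
(0/0) also scores 0.  Neighbors without expression data are excluded from
the sum rather than imputed as zero, and unscored nodes are absent from the
result (so they can never be selected downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .expression import ExpressionProfile, align_to_network
from .network_io import PPINetwork


@dataclass
class GibbsScores:
    """Per-node Gibbs contributions for one sample (all values <= 0)."""

    sample_id: str
    G: dict[str, float] = field(default_factory=dict)


def gibbs_energy(network: PPINetwork, profile: ExpressionProfile) -> GibbsScores:
    """Score every covered network node for one sample.

    Raises
    ------
    CoverageError
        If the profile covers no network node.
    """
    report = align_to_network(profile, network)
    c = profile.c
    G: dict[str, float] = {}
    for i in report.covered_nodes:
        ci = c[i]
        if ci <= 0.0:
            G[i] = 0.0
            continue
        s = ci + sum(c[j] for j in network.graph.neighbors(i) if j in c)
        # ci > 0 implies s >= ci > 0
        G[i] = ci * math.log(ci / s)
    return GibbsScores(sample_id=profile.sample_id, G=G)


def scores_frame(
    network: PPINetwork, profile: ExpressionProfile, scores: GibbsScores
) -> pd.DataFrame:
    """Tabulate one sample's scores, most negative first.

    Columns: node, c, degree, covered_degree, G; sorted by ascending G then
    node identifier, so the top row is the anchor candidate.
    """
    rows = []
    for node, g in scores.G.items():
        nbrs = set(network.graph.neighbors(node))
        rows.append(
            {
                "node": node,
                "c": profile.c[node],
                "degree": len(nbrs),
                "covered_degree": sum(1 for j in nbrs if j in profile.c),
                "G": g,
            }
        )
    df = pd.DataFrame(rows, columns=["node", "c", "degree", "covered_degree", "G"])
    return df.sort_values(["G", "node"], kind="mergesort").reset_index(drop=True)
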