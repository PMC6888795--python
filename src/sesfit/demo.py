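"""A stylized demo network of urban lake governance.

SYNTHETIC RECONSTRUCTION. The observed Bengaluru lake-group network that
motivated this package was never published in machine-readable form (it
exists only as a figure and appendix summaries), so this module ships a
hand-designed stand-in with the same marginal structure: 23 lake groups
(A-W; three MOU groups G, I and L, seven 1st-generation, thirteen
2nd-generation) working with 29 lakes arranged as three watershed chains.
Its edge lists are invented, tuned so the qualitative signature of the
study system holds -- lake-chain groups over-represented, non-collaborative
lake sharing and work on unconnected lakes under-represented, MOU hubs
dominating the central communication position e-1 and the external-support
position g-2. Quantities computed on it are properties of this
reconstruction, not of the unpublished observed network.
"""

from __future__ import annotations

from .network import ActorCategory as C
from .network import ActorNode, EcoNode, SESNetwork

# three watershed chains: W1 = L01..L10, W2 = L11..L20, W3 = L21..L29
_WATERSHEDS = {"W1": range(1, 11), "W2": range(11, 21), "W3": range(21, 30)}

_ACTORS = [
    # 1st generation (founded before formal co-management agreements)
    ("A", C.FIRST_GEN, 1995),
    ("B", C.FIRST_GEN, 1998),
    ("C", C.FIRST_GEN, 2001),
    ("D", C.FIRST_GEN, 2003),
    ("E", C.FIRST_GEN, 2005),
    ("F", C.FIRST_GEN, 2007),
    ("H", C.FIRST_GEN, 2008),
    # MOU groups
    ("G", C.MOU, 2006),
    ("I", C.MOU, 2009),
    ("L", C.MOU, 2010),
    # 2nd generation
    ("J", C.SECOND_GEN, 2010),
    ("K", C.SECOND_GEN, 2011),
    ("M", C.SECOND_GEN, 2011),
    ("N", C.SECOND_GEN, 2011),
    ("O", C.SECOND_GEN, 2012),
    ("P", C.SECOND_GEN, 2012),
    ("Q", C.SECOND_GEN, 2012),
    ("R", C.SECOND_GEN, 2012),
    ("S", C.SECOND_GEN, 2013),
    ("T", C.SECOND_GEN, 2013),
    ("U", C.SECOND_GEN, 2013),
    ("V", C.SECOND_GEN, 2013),
    ("W", C.SECOND_GEN, 2013),
]

# group -> lakes worked with; multi-lake groups hold hydrologically
# adjacent pairs (lake chains); every lake has at most one group, so no
# shared-lake blocks occur in the reconstruction
_MEMBERSHIP = {
    "H": ["L01", "L02"],
    "A": ["L03"],
    "J": ["L04", "L05"],
    "B": ["L06"],
    "G": ["L07"],
    "T": ["L08"],
    "C": ["L09"],
    "D": ["L10"],
    "Q": ["L11", "L12"],
    "E": ["L13"],
    "S": ["L14", "L15"],
    "F": ["L16"],
    "L": ["L17"],
    "P": ["L18"],
    "K": ["L19"],
    "M": ["L20"],
    "U": ["L21", "L22"],
    "N": ["L23"],
    "I": ["L24"],
    "O": ["L25"],
    "R": ["L26"],
    "V": ["L27"],
    "W": ["L28"],
}

# collaboration ties: G and I are hubs; chain groups are supported by an
# MOU group (and occasionally by each other); G-T and L-P pair a senior
# group with a newer one on adjacent lakes (lake chain collaborations)
_SOCIAL = [
    ("G", "H"),
    ("G", "J"),
    ("G", "U"),
    ("G", "T"),
    ("G", "I"),
    ("G", "K"),
    ("G", "M"),
    ("G", "N"),
    ("G", "O"),
    ("G", "R"),
    ("I", "Q"),
    ("I", "S"),
    ("I", "V"),
    ("I", "W"),
    ("L", "P"),
    ("J", "Q"),
]


def demo_network() -> SESNetwork:
    """Build the stylized 23-group / 29-lake demo network."""
    ecos = [
        EcoNode(f"L{i:02d}", watershed=w)
        for w, rng in _WATERSHEDS.items()
        for i in rng
    ]
    eco_edges = []
    for w, rng in _WATERSHEDS.items():
        ids = [f"L{i:02d}" for i in rng]
        eco_edges.extend(zip(ids, ids[1:]))
    actors = [ActorNode(a, cat, year) for a, cat, year in _ACTORS]
    membership = [(a, l) for a, lakes in _MEMBERSHIP.items() for l in lakes]
    return SESNetwork.from_parts(
        actors=actors,
        ecos=ecos,
        social_edges=_SOCIAL,
        eco_edges=eco_edges,
        membership_edges=membership,
    )
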