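"""The 14-taxon early-angiosperm species tree used by the ILS analysis.

Topology: Amborella and Euryale (Nymphaeales) successively sister to all other
angiosperms; within Mesangiospermae, magnoliids and monocots successively
sister to (Ceratophyllum, eudicots); Ginkgo is the gymnosperm outgroup.

Two focal internal branches drive the discordance analysis:

* branch i   — subtends (Euryale + Mesangiospermae); its four neighbours are
  Amborella, Ginkgo, Euryale and Mesangiospermae, so the three arrangements
  are "Amborella diverges first" (concordant), "Amborella sister to Euryale",
  and "Euryale diverges first".
* branch iii — subtends (Ceratophyllum + eudicots); the alternates join
  Ceratophyllum with monocots or with the magnoliid side.

Branch lengths are in coalescent units, terminals 1 (one allele per species).
"""

from __future__ import annotations

from .msc import SpeciesTree

EUDICOTS = ["Aquilegia", "Vitis", "Arabidopsis", "Prunus"]
MONOCOTS = ["Phalaenopsis", "Musa", "Oryza"]
MAGNOLIIDS = ["Liriodendron", "Cinnamomum", "Persea"]
OUTGROUP = "Ginkgo"

#: clade subtended by focal branch i (Euryale + Mesangiospermae)
BRANCH_I = frozenset(["Euryale"] + EUDICOTS + MONOCOTS + MAGNOLIIDS + ["Ceratophyllum"])
#: clade subtended by focal branch iii (Ceratophyllum + eudicots)
BRANCH_III = frozenset(["Ceratophyllum"] + EUDICOTS)

#: coalescent-unit lengths of the focal branches, obtained by inverting the
#: MSC expectation q1 = 1 - (2/3)exp(-t) at the empirical concordant
#: frequencies 46.3% (branch i) and 39.7% (branch iii)
BRANCH_I_LENGTH = 0.2163
BRANCH_III_LENGTH = 0.1004

FOCAL_CLADES = {"i": BRANCH_I, "iii": BRANCH_III}

#: empirical topology frequencies (%) around the focal branches, measured on
#: the study's 1,374 single-copy nuclear gene trees (all-codon-position set):
#: q1 = species-tree arrangement, q2/q3 the two alternates
EMPIRICAL_Q = {
    "i": (46.3, 27.2, 26.5),
    "iii": (39.7, 27.6, 32.7),
}


def angiosperm_tree(
    branch_i: float = BRANCH_I_LENGTH,
    branch_iii: float = BRANCH_III_LENGTH,
    background: float = 5.0,
    terminal: float = 1.0,
) -> SpeciesTree:
    """Build the study species tree with configurable focal branch lengths.

    Non-focal internal branches are set to ``background`` coalescent units
    (long enough that discordance is confined to the focal branches), terminal
    branches to ``terminal``.
    """
    b, t = background, terminal
    eud = f"(((Arabidopsis:{t},Prunus:{t}):{b},Vitis:{t}):{b},Aquilegia:{t})"
    mono = f"((Musa:{t},Oryza:{t}):{b},Phalaenopsis:{t})"
    mag = f"((Cinnamomum:{t},Persea:{t}):{b},Liriodendron:{t})"
    cer_eud = f"(Ceratophyllum:{t},{eud}:{b})"
    mesa = f"({mag}:{b},({mono}:{b},{cer_eud}:{branch_iii}):{b})"
    angio = f"(Euryale:{t},{mesa}:{b})"
    newick = f"(Ginkgo:{t},(Amborella:{t},{angio}:{branch_i}):{b});"
    return SpeciesTree.from_newick(newick)
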