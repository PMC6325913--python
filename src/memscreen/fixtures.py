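"""Packaged toy network and annotation fixtures.

These are small SYNTHETIC networks hand-built so that the documented
connectivity facts of the screen's hit sets hold on them — they are not
exports of any external functional-relationship database:

* acute network: at confidence >= 0.85, ft and knrl sit in one connected
  developmental subnetwork while TkR86C retains exactly one partner,
  l(1)G0020;
* memory network: at confidence >= 0.85 the memory hits are densely
  interconnected with known learning-and-memory genes (FMR1, dnc, amn,
  Adf1, Gug) while Nrk is isolated; lowering the threshold to 0.4 connects
  Nrk to the network.

The toy annotation map carries learning/memory and developmental process
terms over a small synthetic background, for exercising the enrichment
stage end to end.
"""

from __future__ import annotations

from .network import AnnotationMap, FunctionalNetwork

__all__ = ["toy_acute_network", "toy_memory_network", "toy_annotations"]

ACUTE_HITS = ("ft", "knrl", "TkR86C")
MEMORY_HITS = (
    "sens", "rut", "sna", "5-HT7", "Rnp4F", "Nrk", "Cad87A", "Dop1R1",
    "Octbeta1R", "Mob4", "mnb", "Dop1R2",
)

_ACUTE_EDGES = [
    # ft / knrl developmental neighborhood, stringent tier
    ("ft", "ds", 0.97),
    ("ft", "fj", 0.93),
    ("ft", "ex", 0.90),
    ("ft", "sal", 0.88),
    ("knrl", "kni", 0.95),
    ("knrl", "sal", 0.91),
    ("knrl", "hh", 0.87),
    ("ds", "fj", 0.92),
    ("ex", "hh", 0.86),
    # TkR86C: one stringent partner, plus weak-only edges
    ("TkR86C", "l(1)G0020", 0.90),
    ("TkR86C", "Takr99D", 0.55),
    ("TkR86C", "Tk", 0.47),
]

_MEMORY_EDGES = [
    # dense stringent core among hits and known memory genes
    ("rut", "dnc", 0.98),
    ("rut", "amn", 0.96),
    ("rut", "FMR1", 0.90),
    ("dnc", "amn", 0.95),
    ("dnc", "FMR1", 0.93),
    ("FMR1", "Adf1", 0.89),
    ("Adf1", "Gug", 0.88),
    ("sens", "sna", 0.92),
    ("sens", "Gug", 0.86),
    ("sna", "Adf1", 0.87),
    ("5-HT7", "Dop1R1", 0.91),
    ("Dop1R1", "Dop1R2", 0.94),
    ("Dop1R2", "Octbeta1R", 0.89),
    ("Octbeta1R", "5-HT7", 0.88),
    ("Dop1R1", "dnc", 0.87),
    ("Mob4", "mnb", 0.90),
    ("mnb", "FMR1", 0.86),
    ("Mob4", "rut", 0.85),
    ("Cad87A", "sens", 0.86),
    ("Rnp4F", "FMR1", 0.85),
    # Nrk connects only below the stringent tier
    ("Nrk", "dnc", 0.62),
    ("Nrk", "Adf1", 0.55),
    ("Nrk", "mnb", 0.44),
]

# term -> genes, over a synthetic background
_TOY_TERMS = {
    "associative learning": ["rut", "dnc", "amn", "FMR1", "Dop1R1", "mnb"],
    "learning": ["rut", "dnc", "amn", "FMR1", "Dop1R1", "5-HT7", "mnb"],
    "long-term memory": ["rut", "dnc", "amn", "Adf1", "Gug", "Mob4"],
    "olfactory learning": ["rut", "dnc", "Dop1R2", "Octbeta1R"],
    "cell fate specification": ["ft", "knrl", "sens", "sna", "kni", "sal"],
    "cell fate commitment involved in pattern formation": ["ft", "knrl", "kni"],
    "neuroblast differentiation": ["sens", "sna", "ds"],
    "neuropeptide signaling pathway": ["TkR86C", "l(1)G0020", "Takr99D", "Tk"],
    "signal transduction": ["ft", "ex", "hh", "5-HT7", "Dop1R1", "Dop1R2",
                            "Octbeta1R", "TkR86C", "Nrk"],
}

#: Unannotated filler genes padding the toy background universe.
_TOY_BACKGROUND_FILLERS = [f"bg{i:02d}" for i in range(1, 21)]


def toy_acute_network() -> FunctionalNetwork:
    """Synthetic acute-hit network (ft/knrl connected, TkR86C one stringent partner)."""
    return FunctionalNetwork(_ACUTE_EDGES)


def toy_memory_network() -> FunctionalNetwork:
    """Synthetic memory-hit network (dense stringent core, Nrk weak-tier only)."""
    return FunctionalNetwork(_MEMORY_EDGES)


def toy_annotations() -> AnnotationMap:
    """Synthetic gene -> process-term map over a small background universe.

    Filler genes pad the background with one generic term each so that the
    background size exceeds the annotated hit neighborhoods.
    """
    pairs = [(g, term) for term, genes in _TOY_TERMS.items() for g in genes]
    pairs.extend((g, "generic metabolic process") for g in _TOY_BACKGROUND_FILLERS)
    return AnnotationMap.from_pairs(pairs)
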