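import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ppi_evorate.annotation import FunctionalAnnotation
from ppi_evorate.complexes import ComplexCatalog
from ppi_evorate.distance import AlignedOrthologPair
from ppi_evorate.network import InteractionNetwork


@pytest.fixture
def triangle_net() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def star_net() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("hub", f"leaf{i}") for i in range(5)])


def brute_force_clustering(net: InteractionNetwork, p: str):
    """Independent oracle: enumerate all neighbour pairs and count interactions."""
    neigh = sorted(net.neighbors(p))
    v = len(neigh)
    if v < 2:
        return None
    l = 0
    for i in range(v):
        for j in range(i + 1, v):
            if frozenset((neigh[i], neigh[j])) in net.edges:
                l += 1
    return 2 * l / (v * (v - 1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# --- the 10-protein hand-built fixture -------------------------------------
# Topology (worked out by hand):
#   triangle P1-P2-P3, chain P3-P4-P5, triangle P6-P7-P8 with pendant P6-P9,
#   P10 isolated.

HAND_EDGES = [
    ("P1", "P2"), ("P1", "P3"), ("P2", "P3"),
    ("P3", "P4"), ("P4", "P5"),
    ("P6", "P7"), ("P6", "P8"), ("P7", "P8"), ("P6", "P9"),
]

HAND_CLASSES = {
    "P1": {"Metabolism"},
    "P2": {"Metabolism"},
    "P3": {"Metabolism", "Energy"},
    "P4": {"Energy"},
    "P5": {"Transcription"},
    "P6": {"Transcription"},
    "P7": {"Transcription"},
    "P8": {"Metabolism"},
    "P9": {"Transcription"},
    # P10 unannotated
}

HAND_COMPLEXES = {
    "C1": {"P1", "P2", "P3"},
    "C2": {"P1", "P6"},
    "C3": {"P4"},
}

HAND_EXPRESSION = {
    "P1": 5.0, "P2": 4.0, "P3": 3.5, "P4": 2.0, "P5": 1.0,
    "P6": 3.0, "P7": 2.5, "P8": 1.5, "P9": 0.8, "P10": 0.5,
}

# per-protein aligned ortholog pairs with hand-countable differences
HAND_ALIGNMENTS = {
    "P1": ("ACDEFGHIKL", "ACDEFGHIKL"),   # p = 0
    "P2": ("ACDEFGHIKL", "ACDEFGHIKV"),   # p = 1/10
    "P3": ("ACDEFGHIKL", "MCDEFGHIKV"),   # p = 2/10
    "P4": ("AC-EFGHIKL", "ACDEFGHIKV"),   # 9 ungapped cols, 1 diff -> p = 1/9
    "P5": ("WWWWW", "WWWWW"),
    "P6": ("ACDEF", "ACDEF"),
    "P7": ("ACDEF", "ACDEF"),
    "P8": ("ACDEF", "ACDEF"),
    "P9": ("ACDEF", "ACDEF"),
    "P10": ("ACDEF", "ACDEF"),
}


@pytest.fixture
def hand_network() -> InteractionNetwork:
    net = InteractionNetwork.from_edges(HAND_EDGES)
    net.add_protein("P10")
    return net


@pytest.fixture
def hand_annotation() -> FunctionalAnnotation:
    ann = FunctionalAnnotation()
    for protein, labels in HAND_CLASSES.items():
        for label in labels:
            ann.add(protein, label)
    return ann


@pytest.fixture
def hand_catalog() -> ComplexCatalog:
    cat = ComplexCatalog()
    for cid, members in HAND_COMPLEXES.items():
        for protein in members:
            cat.add(cid, protein)
    return cat


@pytest.fixture
def hand_pairs() -> list[AlignedOrthologPair]:
    return [
        AlignedOrthologPair(pid, f"{pid}_orth", a, b)
        for pid, (a, b) in HAND_ALIGNMENTS.items()
    ]
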