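import pytest
from hypothesis import HealthCheck, settings

from oralvirome.assignment import assign_all
from oralvirome.io import AlignmentHit
from oralvirome.simulate import simulate_fixture, small_fixture_model
from oralvirome.taxonomy import TaxonNode, TaxonomyTree

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_hit(
    query="q1",
    subject="ref|s1",
    identity=95.0,
    length=200,
    evalue=1e-10,
    bits=300.0,
    qlen=250,
    db="viral",
):
    return AlignmentHit(query, subject, identity, length, evalue, bits, qlen, db)


@pytest.fixture
def toy_tree():
    """Two-order forest with sibling species and all three viral classes.

    o1 ── f1 ── g1 ── s1, s2   (prophage family)
    │          g2 ── s3        (same family, other genus)
    │    f2 ── g3 ── s4        (eukaryotic-virus family)
    o2 ── f3 ── g4 ── s5       (bacteriophage family)
    """
    nodes = [
        TaxonNode("o1", "Caudovirales", "order", None),
        TaxonNode("f1", "Siphoviridae", "family", "o1"),
        TaxonNode("g1", "Lambdavirus", "genus", "f1"),
        TaxonNode("s1", "Phage A", "species", "g1"),
        TaxonNode("s2", "Phage B", "species", "g1"),
        TaxonNode("g2", "Tequatrovirus", "genus", "f1"),
        TaxonNode("s3", "Phage C", "species", "g2"),
        TaxonNode("f2", "Herpesviridae", "family", "o1"),
        TaxonNode("g3", "Roseolovirus", "genus", "f2"),
        TaxonNode("s4", "Human herpesvirus 7", "species", "g3"),
        TaxonNode("o2", "Petitvirales", "order", None),
        TaxonNode("f3", "Microviridae", "family", "o2"),
        TaxonNode("g4", "Microvirus", "genus", "f3"),
        TaxonNode("s5", "Phage D", "species", "g4"),
    ]
    subjects = {
        "ref|s1": ("s1", "prophage"),
        "ref|s2": ("s2", "prophage"),
        "ref|s3": ("s3", "prophage"),
        "ref|s4": ("s4", "eukaryotic_virus"),
        "ref|s5": ("s5", "bacteriophage"),
    }
    return TaxonomyTree(nodes, subjects)


class SmallSim:
    """A 12-sample, ~5k-read fixture with ground truth and assignments."""

    def __init__(self):
        self.model, self.tree = small_fixture_model(seed=0)
        self.truth, self.hits = simulate_fixture(self.model, self.tree, 0)
        self.assignments = {
            s: assign_all(self.hits.viral[s], self.hits.bacterial[s], self.tree)
            for s in self.truth.counts.columns
        }
        self.per_sample = {
            s: r.assignments for s, r in self.assignments.items()
        }


@pytest.fixture(scope="session")
def small_sim():
    return SmallSim()
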