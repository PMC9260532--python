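import pytest

from cigpath import GuidelineModel, VertexType, generate_pattern


@pytest.fixture(scope="session")
def sync_fixture():
    """Synchronization pattern: AND-split to tasks A and B, AND-join guarded
    on their recorded outcomes, then task C."""
    return generate_pattern("synchronization")


@pytest.fixture()
def chain_model():
    """start -> T1 -> T2 -> T3 -> end, no conditions."""
    m = GuidelineModel(id="chain")
    m.add_vertex("start", VertexType.START)
    for t in ("T1", "T2", "T3"):
        m.add_vertex(t, VertexType.TASK)
    m.add_vertex("end", VertexType.END)
    names = ["start", "T1", "T2", "T3", "end"]
    for i, (u, v) in enumerate(zip(names, names[1:]), 1):
        m.add_edge(f"f{i}", u, v)
    return m


@pytest.fixture()
def loop_model():
    """start -> join -> T1 -> split -> (back to join if T1 == false | T2) -> end."""
    m = GuidelineModel(id="loop")
    m.add_vertex("start", VertexType.START)
    m.add_vertex("j", VertexType.XOR_GATEWAY)
    m.add_vertex("T1", VertexType.TASK)
    m.add_vertex("s", VertexType.XOR_GATEWAY)
    m.add_vertex("T2", VertexType.TASK)
    m.add_vertex("end", VertexType.END)
    m.add_edge("f1", "start", "j")
    m.add_edge("f2", "j", "T1")
    m.add_edge("f3", "T1", "s")
    m.add_edge("f4", "s", "j", condition="T1 == false")
    m.add_edge("f5", "s", "T2")
    m.add_edge("f6", "T2", "end")
    return m
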