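import pandas as pd
import pytest

from culttrans import NetworkTable


def make_table(rows, **kwargs):
    """Build a NetworkTable from (network_id, role, factor, score) tuples."""
    df = pd.DataFrame(rows, columns=["network_id", "role", "factor", "score"])
    return NetworkTable(df, **kwargs)


def binary_net(nid, student, vertical, horizontal, factor="F"):
    """One fully observed network with signed (+1/-1) trait scores whose
    parental components dichotomise to the given 0/1 indicators."""
    s = lambda t: 1.0 if t else -1.0
    return [
        (nid, "student", factor, s(student)),
        (nid, "mother", factor, s(vertical)),
        (nid, "father", factor, s(vertical)),
        (nid, "friend1", factor, s(horizontal)),
        (nid, "friend2", factor, s(horizontal)),
    ]


def table_with_counts(P, N, factor="F"):
    """A NetworkTable whose transmission table has exactly counts P, N."""
    rows = []
    i = 0
    for t, p in P.items():
        v = 1 if t[0] == "V" else 0
        h = 1 if t[1] == "H" else 0
        for j in range(p):
            rows += binary_net(f"n{i:05d}", int(j < N[t]), v, h, factor)
            i += 1
    return make_table(rows)


@pytest.fixture
def tiny_table():
    """Two networks, two factors, mixed composition."""
    rows = []
    for f in ("Religiosity", "Politics"):
        rows += [
            ("net1", "student", f, 0.5),
            ("net1", "mother", f, 0.4),
            ("net1", "father", f, -0.2),
            ("net1", "friend1", f, 0.1),
            ("net2", "student", f, -0.3),
            ("net2", "mother", f, 0.4),
        ]
    return make_table(rows)
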