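import pandas as pd
import pytest

from fedres.disclosure import DisclosureConfig
from fedres.federation import ClientSession, ServerNode


def build_session(envs, disclosure=None, allowed_ops=None, names=None):
    """Assemble an in-process session; ``envs`` is one environment mapping
    (symbol -> dataset) per node."""
    nodes = []
    for k, env in enumerate(envs):
        node = ServerNode(
            names[k] if names else f"study{k}",
            disclosure=disclosure,
            allowed_ops=allowed_ops,
        )
        node.environment.update(env)
        nodes.append(node)
    return ClientSession(nodes)


@pytest.fixture
def session_factory():
    return build_session


@pytest.fixture
def tiny_table():
    return pd.DataFrame({"a": [1, 2, 3], "b": [4.5, 5.5, 6.5]})


@pytest.fixture
def off_config():
    return DisclosureConfig(mode="off")


@pytest.fixture
def minimal_config():
    return DisclosureConfig(mode="minimal")


@pytest.fixture
def full_config():
    return DisclosureConfig(mode="full")
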