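from __future__ import annotations

import pytest

from repviz import fixtures


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """One deterministic demo bundle shared by rendering/CLI tests."""
    out = tmp_path_factory.mktemp("demo")
    return fixtures.demo_scene(out, seed=1)


@pytest.fixture()
def bam_factory(tmp_path):
    """Write a FixtureSpec to an indexed BAM inside the test's tmp dir."""
    counter = {"n": 0}

    def _make(spec: fixtures.FixtureSpec):
        counter["n"] += 1
        return fixtures.write_bam(spec, tmp_path / f"fixture{counter['n']}.bam")

    return _make
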