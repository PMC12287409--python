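import pytest

from knockoutkit.synthetic_data import ikba_demo


@pytest.fixture(scope="session")
def ikba():
    """The flagship synthetic PTM fixture (built once per session)."""
    return ikba_demo(seed=3)


@pytest.fixture()
def write(tmp_path):
    """Write text content to a temp file and return its path."""

    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content, encoding="utf-8")
        return p

    return _write
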