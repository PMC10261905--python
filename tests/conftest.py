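import logging

import pytest

from ilama.defaults import default_panel, default_protocol
from ilama.simulate import WITH_COMPETITION, WITHOUT_COMPETITION

logging.getLogger("ilama").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def protocol_with():
    return default_protocol(WITH_COMPETITION)


@pytest.fixture(scope="session")
def protocol_without():
    return default_protocol(WITHOUT_COMPETITION)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def count_files(tmp_path):
    """Write a small well-formed count + totals fixture, return the paths."""

    def _write(count_rows, total_rows):
        counts = tmp_path / "counts.tsv"
        totals = tmp_path / "totals.tsv"
        counts.write_text(
            "clone_id\tarm\tround\treads\n"
            + "".join(f"{c}\t{a}\t{r}\t{n}\n" for c, a, r, n in count_rows)
        )
        totals.write_text(
            "arm\tround\ttotal_reads\n"
            + "".join(f"{a}\t{r}\t{n}\n" for a, r, n in total_rows)
        )
        return counts, totals

    return _write
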