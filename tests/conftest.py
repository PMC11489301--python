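import pytest

from fusionframe.synthetic_data import (
    load_case_metadata,
    load_cytobands,
    load_reference_models,
    make_case_fixtures,
)


@pytest.fixture(scope="session")
def models():
    return load_reference_models()


@pytest.fixture(scope="session")
def bundles():
    return make_case_fixtures()


@pytest.fixture(scope="session")
def metadata():
    return load_case_metadata()


@pytest.fixture(scope="session")
def cytobands():
    return load_cytobands()


@pytest.fixture()
def toy_gtf(tmp_path):
    """Tiny two-gene GTF: PLUSG (+, 3 exons) and MINUSG (-, 3 exons)."""
    attr_p = 'gene_id "PLUSG"; gene_name "PLUSG"; transcript_id "P-1";'
    attr_m = 'gene_id "MINUSG"; gene_name "MINUSG"; transcript_id "M-1";'
    lines = []
    for s, e in [(101, 200), (301, 400), (501, 600)]:
        lines.append(f"chr1\ttoy\texon\t{s}\t{e}\t.\t+\t.\t{attr_p}")
        lines.append(f"chr1\ttoy\tCDS\t{s}\t{e}\t.\t+\t0\t{attr_p}")
    for s, e in [(1101, 1200), (1301, 1400), (1501, 1600)]:
        lines.append(f"chr2\ttoy\texon\t{s}\t{e}\t.\t-\t.\t{attr_m}")
        lines.append(f"chr2\ttoy\tCDS\t{s}\t{e}\t.\t-\t0\t{attr_m}")
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
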