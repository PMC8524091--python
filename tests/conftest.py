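import numpy as np
import pytest

from hybriqc.genotype_io import GenotypeMatrix, MarkerDef, default_panel

# compact call-state notation used throughout the tests:
# A = homozygous allele1, H = het, B = homozygous allele2, - = missing
CODE = {"A": 0, "H": 1, "B": 2, "-": -1}


def make_panel(n: int) -> list[MarkerDef]:
    """n synthetic T/C markers spread over chromosomes 1..n."""
    return [MarkerDef(marker_id=f"m{j + 1:02d}", chromosome=j + 1,
                      pos_start=1000 * (j + 1), pos_end=1000 * (j + 1) + 100,
                      allele1="T", allele2="C")
            for j in range(n)]


def matrix_from_strings(rows: dict[str, str],
                        panel: list[MarkerDef] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {sample_id: 'AHB-...'} state strings."""
    n = len(next(iter(rows.values())))
    if panel is None:
        panel = make_panel(n)
    calls = np.array([[CODE[c] for c in s] for s in rows.values()],
                     dtype=np.int8)
    return GenotypeMatrix(sample_ids=list(rows), panel=panel, calls=calls)


@pytest.fixture(scope="session")
def qc_panel():
    return default_panel()
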