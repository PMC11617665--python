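import textwrap

import pytest
from hypothesis import settings

from repurpose.library import parse_library

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


LIBRARY_CSV = textwrap.dedent(
    """\
    id,smiles,activity_um,activity_type,source_class
    benzene,c1ccccc1,10,IC50,PTP1B
    estradiol,C[C@]12CC[C@H]3[C@@H](CCc4cc(O)ccc43)[C@@H]1CC[C@@H]2O,5,IC50,PTP1B
    naphthol,Oc1ccc2ccccc2c1,50,IC50,PTP1B
    naphthol_salt,Oc1ccc2ccccc2c1.[Na+].[Cl-],5,IC50,PTP1B
    weak,Cc1ccc2ccccc2c1,150,IC50,PTP1B
    aspirin,CC(=O)Oc1ccccc1C(=O)O,,none,drug
    hexane,CCCCCC,20,IC50,PTP1B
    """
)

# second molecule has no id property and a blank name line
SDF_TWO_MOLECULES = (
    "mol_one\n     RDKit          2D\n\n"
    "  6  6  0  0  0  0  0  0  0  0999 V2000\n"
    "    0.0000    1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "    0.8660    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "    0.8660   -0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "    0.0000   -1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "   -0.8660   -0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "   -0.8660    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "  1  2  2  0\n  2  3  1  0\n  3  4  2  0\n  4  5  1  0\n  5  6  2  0\n  6  1  1  0\n"
    "M  END\n"
    "> <id>\nbenzene_sdf\n\n$$$$\n"
    "\n     RDKit          2D\n\n"
    "  2  1  0  0  0  0  0  0  0  0999 V2000\n"
    "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "    1.5000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0\n"
    "  1  2  1  0\n"
    "M  END\n$$$$\n"
)


@pytest.fixture
def library_csv(tmp_path):
    path = tmp_path / "library.csv"
    path.write_text(LIBRARY_CSV)
    return path


@pytest.fixture
def small_library(library_csv):
    return parse_library(library_csv, "csv")


@pytest.fixture
def sdf_file(tmp_path):
    path = tmp_path / "two.sdf"
    path.write_text(SDF_TWO_MOLECULES)
    return path
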