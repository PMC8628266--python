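import pytest

from ritpipe.nuclides import builtin_nuclide


@pytest.fixture(scope="session")
def y90():
    return builtin_nuclide("Y-90")


@pytest.fixture(scope="session")
def in111():
    return builtin_nuclide("In-111")


@pytest.fixture
def biodist_csv(tmp_path):
    """Small well-formed biodistribution table on disk."""
    path = tmp_path / "biodist.csv"
    path.write_text(
        "animal_id,group,organ,time_h,percent_id_per_g,body_weight_g\n"
        "a1,saline,tumor,1,1.7,20\n"
        "a2,saline,tumor,1,3.2,20\n"
        "a3,saline,tumor,1,4.7,20\n"
    )
    return path
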