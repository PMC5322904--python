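import pytest

from isotail.refsets import MiRNARef, ReferenceSet
from isotail.synthetic import demo_reference

# 21-nt mature used throughout the classifier examples
MATURE_T = "AUCGAUCGAUCGAUCGAUCGA"


@pytest.fixture(scope="session")
def mini_ref() -> MiRNARef:
    """One mature embedded in a hairpin with known downstream context."""
    hairpin = "CCU" + MATURE_T + "GGCAUUACG"
    return MiRNARef(
        group_name="miRT",
        member_names=("miRT",),
        mature_seq=MATURE_T,
        hairpin_name="MIRT",
        hairpin_seq=hairpin,
        mature_offset=3,
    )


@pytest.fixture(scope="session")
def mini_refset(mini_ref) -> ReferenceSet:
    return ReferenceSet(refs=[mini_ref])


@pytest.fixture(scope="session")
def refset() -> ReferenceSet:
    """The built-in synthetic demo reference (11 groups)."""
    return demo_reference()


@pytest.fixture
def fasta_pair(tmp_path):
    """Write mature/hairpin FASTA files on demand; returns a factory."""

    def _write(matures: dict[str, str], hairpins: dict[str, str]):
        mpath = tmp_path / "mature.fa"
        hpath = tmp_path / "hairpin.fa"
        mpath.write_text("".join(f">{k}\n{v}\n" for k, v in matures.items()))
        hpath.write_text("".join(f">{k}\n{v}\n" for k, v in hairpins.items()))
        return mpath, hpath

    return _write
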