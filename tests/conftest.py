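import numpy as np
import pytest
from hypothesis import settings

from cffvar.model import AnnotatedVariant, GenotypeMatrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_vcf(tmp_path):
    """3-sample, 2-site VCF with one het, one missing and one multi-allelic-free record."""
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trs1\tA\tG\t50\tPASS\t.\tGT\t0/1\t./.\t1/1\n"
        "1\t200\trs2\tC\tT\t50\tPASS\t.\tGT\t0/0\t0/1\t0/0\n"
    )
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


def make_variant(**kwargs) -> AnnotatedVariant:
    defaults = dict(
        chrom="1",
        pos=1000,
        ref_allele="A",
        alt_allele="G",
        gene="GENE0001",
        consequence="missense",
    )
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


def make_matrix(dosages, ids=None, keys=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"I{i}" for i in range(n)]
    keys = keys or [f"rs{j}" for j in range(m)]
    return GenotypeMatrix(ids, keys, dosages)
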