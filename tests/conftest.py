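import pytest

from ctcmut.spectra_signatures import toy_catalog
from ctcmut.variant_io import FuncClass, Lesion, MutationRecord


@pytest.fixture(scope="session")
def catalog():
    return toy_catalog()


def make_snv(
    case_id="C1",
    lesion=Lesion.PRIMARY,
    chrom="1",
    pos=100,
    ref="C",
    alt="T",
    gene="",
    func_class=FuncClass.MISSENSE,
    context=None,
    alt_depth=None,
    ref_depth=None,
):
    if context is None:
        context = f"A{ref}A"
    return MutationRecord(
        case_id=case_id,
        lesion=lesion,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        func_class=func_class,
        context=context,
        alt_depth=alt_depth,
        ref_depth=ref_depth,
    )


THREE_CASE_MAF = """\
case_id	lesion	chrom	pos	ref	alt	gene	func_class	context	alt_depth	ref_depth
A	primary	1	100	C	T	KMT2C	missense	ACA	10	10
A	primary	1	200	C	A	TP53	silent	GCG	8	12
A	primary	1	300	T	G	RB1	missense	ATA	5	15
A	ctc	1	200	C	A	TP53	silent	GCG	9	11
A	ctc	1	300	T	G	RB1	missense	ATA	6	14
A	ctc	1	400	G	A	EP300	nonsense	AGT	7	13
B	primary	2	100	C	T	KMT2C	missense	TCT	10	10
B	primary	2	200	T	C	ASXL1	silent	CTC	10	10
B	ctc	2	100	C	T	KMT2C	missense	TCT	12	8
B	ctc	2	200	T	C	ASXL1	silent	CTC	11	9
C	primary	3	100	C	G	KMT2C	missense	TCA	10	10
C	ctc	3	200	G	C	TET1	missense	AGT	10	10
"""


@pytest.fixture
def three_case_maf(tmp_path):
    """Hand-built cohort: case A concordance 1/2, case B 1, case C 0."""
    path = tmp_path / "three_case.maf.tsv"
    path.write_text(THREE_CASE_MAF)
    return path
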