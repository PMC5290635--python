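import pytest

from longevol import synthetic_data as sd


def make_vcf(tmp_path, body_lines, sample="S1", name="test.vcf"):
    """Write a minimal VCF v4.2 with the given body lines."""
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        "##contig=<ID=chr7>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="e">',
        '##INFO=<ID=TNC,Number=1,Type=String,Description="t">',
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="p">',
        '##INFO=<ID=CODING,Number=0,Type=Flag,Description="c">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    path = tmp_path / name
    path.write_text("\n".join(header + list(body_lines)) + "\n")
    return path


@pytest.fixture(scope="session")
def patient():
    """One simulated 4-clone serial-tumor patient (default study conditions)."""
    return sd.simulate_patient(seed=11)


@pytest.fixture(scope="session")
def ccf_matrix(patient):
    from longevol.clonality import assemble_ccf_matrix

    return assemble_ccf_matrix(
        patient.variants_by_timepoint,
        patient.segments_by_timepoint,
        patient.metas,
        site_depth=patient.site_depth,
    )
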