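"""Shared helpers for acceptance-level tests."""

from nkaml import PatientProfile


def _profile(pid, genes=(), biallelic=False, r172=False, n=None):
    genes = frozenset(genes)
    return PatientProfile(
        patient_id=pid,
        mutated_genes=genes,
        n_driver_mutations=len(genes) if n is None else n,
        biallelic_cebpa=biallelic,
        idh2_r172=r172,
    )


def table_one_profiles():
    """A 393-patient cohort with the published subgroup counts."""
    mix = [
        (136, dict(genes={"NPM1"})),
        (42, dict(genes={"SRSF2"})),
        (6, dict(genes={"TP53"})),
        (53, dict(genes={"CEBPA"}, biallelic=True, n=2)),
        (8, dict(genes={"IDH2"}, r172=True)),
        (116, dict(genes={"DNMT3A"})),
        (17, dict(genes=())),
        (15, dict(genes={"NPM1", "TP53"})),
    ]
    profiles = []
    i = 0
    for count, kw in mix:
        for _ in range(count):
            profiles.append(_profile(f"P{i:04d}", **kw))
            i += 1
    return profiles
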