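"""Screen element pairs for horizontal transposon transfer.

Builds one planted transfer case (near-identical elements in hosts from
different phyla, multiple genomic copies in both), one contamination case
(single genomic copy) and one vertical case (same phylum), then runs the
decision table.
"""

from tcmariner.htt_screen import screen_pairs
from tcmariner.synthetic_data import sim_htt_benchmark

cases, taxonomy = sim_htt_benchmark(n_each=1, seed=21)

for case in cases:
    verdicts = screen_pairs(
        [(case.element_a, case.host_a), (case.element_b, case.host_b)],
        taxonomy,
        {case.element_a.id: case.hits_a, case.element_b.id: case.hits_b},
    )
    if not verdicts:
        print(f"{case.kind:>13}: not evaluated (hosts below the phylum gate)")
        continue
    v = verdicts[0]
    ids = v.identities
    print(
        f"{case.kind:>13}: verdict={v.verdict}"
        f"  aaDDE={ids.aa_identity_dde:.1f}%"
        f"  ntORF={ids.nt_identity_transposase:.1f}%"
        f"  copies={v.copy_report_a.copy_count}/{v.copy_report_b.copy_count}"
    )

# A transfer survives every filter (candidate); a single-copy element is
# rejected as a contamination suspect; same-phylum pairs are never
# evaluated because vertical inheritance explains their similarity.
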