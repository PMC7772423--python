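"""Channel-gene differential expression from FPKM pairs.

Loads the packaged 13-gene VGCC/VGKC table, recomputes log2 fold changes,
applies the DEG rule (|log2FC| >= 1 and q <= 0.05) and summarises by
channel family.
"""

from ionclamp import expression

table = expression.load_channel_deg_table()
print(table[["family", "gene", "fpkm_mock", "fpkm_cln1", "log2fc", "q", "is_deg"]]
      .to_string(index=False, float_format=lambda x: f"{x:.2f}"))

counts = expression.family_summary(table)
print(
    f"\nflagged DEGs: {int(table['is_deg'].sum())}/13; "
    f"potassium-channel DEGs: {counts['potassium_total']} "
    f"(of which Kv: {counts['kv']}); VGCC-related: {counts['vgcc_related']}"
)
print(
    "\nlog2FC = log2(FPKM_CLN1 / FPKM_mock): most channel subunit genes are\n"
    "downregulated upon CLN1/PPT1 overexpression, including CACNA2D2\n"
    "(alpha2delta-2, log2FC -1.11) and KCNH4 (Kv12.3, -1.16)."
)
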