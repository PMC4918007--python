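"""Generate a synthetic co-divergence study and inspect its design.

Builds the default study — five clades, two sulfide systems per clade,
two non-sulfidic partner sites per system — and prints the site table
plus the realized habitat contrast in offspring traits.
"""

from sulfidiv import synthetic

sites = synthetic.generate_sites(seed=1)
print(sites[["site_id", "clade", "system_id", "sulfidic", "h2s_um"]].head(6))
print(f"\n{sites.sulfidic.sum()} sulfidic systems, {len(sites)} sites total")

traits = synthetic.generate_traits(sites, n_per_site=24, seed=1)
fem = traits[traits.sex == "F"]
means = fem.groupby("sulfidic")[["embryo_lean_weight_mg", "fecundity"]].mean()
print("\nhabitat means (females):")
print(means.round(2))
print(
    "\nSulfidic females carry larger but fewer embryos; the size of the"
    "\ncontrast scales with each spring's H2S concentration."
)
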