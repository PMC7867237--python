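"""Convert a media recipe into Maximal Uptake Rates (MUR).

The uptake cap of a nutrient is the absolute change of its medium
concentration over the 48 h culture window (mM/48 h).  Without a spent-medium
measurement the final concentration defaults to 0: the cells may consume the
nutrient completely, so the cap equals the initial availability.
"""

from gemprofiler import MediumMeasurement, compute_mur

# glutamine supplied at 4 mM and fully consumed over 48 h
full = MediumMeasurement(
    metabolite="glutamine", exchange_reaction_id="EX_gln_L_e",
    conc_initial=4.0, conc_final=0.0, t_initial=0.0, t_final=48.0,
)
print(f"glutamine 4 mM, fully consumed:   MUR = {compute_mur(full)} mM/48 h")

# glucose supplied at 10 mM with 6 mM left after 48 h (measured consumption)
partial = MediumMeasurement(
    metabolite="glucose", exchange_reaction_id="EX_glc_D_e",
    conc_initial=10.0, conc_final=6.0, t_initial=0.0, t_final=48.0,
)
print(f"glucose 10 -> 6 mM over 48 h:     MUR = {compute_mur(partial)} mM/48 h")

# availability-only mode: a plain recipe entry, final concentration omitted
recipe = MediumMeasurement(
    metabolite="glucose", exchange_reaction_id="EX_glc_D_e", conc_initial=25.0,
)
print(f"glucose 25 mM, availability only: MUR = {compute_mur(recipe)} mM/48 h")

print(
    "\nEach MUR becomes the uptake cap of its exchange reaction: the\n"
    "exchange lower bound is set to -MUR (uptake is negative flux), while\n"
    "the secretion (upper) bound is left untouched."
)
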