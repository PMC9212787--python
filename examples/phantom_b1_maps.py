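"""Adiabatic versus amplitude-modulated refocusing on a digital phantom.

Builds a spherical phantom whose transmit field dips to 0.6x at the centre,
then maps the creatine peak integral per voxel for (a) the adiabatic sech
pair and (b) a generic amplitude-modulated pi pulse.  The adiabatic map is
uniform (flat above threshold); the AM map inherits the B1 dip.
"""

from slowedit.phantom import (
    coefficient_of_variation,
    make_phantom,
    residual_water_map,
    simulate_phantom_maps,
)

phantom = make_phantom("sphere_b1_dip", seed=0)
mask = phantom.concentrations["creatine_ch3"] > 0

adiabatic = simulate_phantom_maps(phantom, "adiabatic_pair")
am = simulate_phantom_maps(phantom, "am_pulse")

cov_ad = coefficient_of_variation(adiabatic, mask)
cov_am = coefficient_of_variation(am, mask)
print(f"creatine map CoV, adiabatic pair : {100 * cov_ad:6.2f} %")
print(f"creatine map CoV, AM pulse       : {100 * cov_am:6.2f} %")
print(f"the AM map is {cov_am / cov_ad:.0f}x less uniform: flip-angle errors "
      "from the B1 dip propagate as ~sin^4, the adiabatic pair is immune")

water = residual_water_map(phantom)
print(f"max residual water efficiency    : {water.values[mask].max():.2e} "
      "(<= 1e-3: implicit suppression holds across the B0 map)")
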