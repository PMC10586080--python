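# Independent straight transcription of the four force expressions,
# written before the package. Values frozen into tests.
import math

R, d, sig, E, gam = 1e-6, 1e-7, 1e3, 1e4, 0.5

hs = 4*math.pi*R*d*sig*math.cos(math.atan(math.sqrt(2*R/d))) \
     + (4/3)*(1/(1-gam**2))*E*math.sqrt(R)*d**1.5
hertz = (4/3)*(1/(1-gam**2))*E*math.sqrt(R)*d**1.5
theta = math.radians(20.0)
sneddon = (2*math.tan(theta)/math.pi)*(1/(1-gam**2))*E*d**2
T, r_cell = 2e-4, 1e-5
cslc = 4*T*(1/r_cell + 1/R)*math.pi*R*d

print(f"hs      = {hs:.12e}")
print(f"hertz   = {hertz:.12e}")
print(f"sneddon = {sneddon:.12e}")
print(f"cslc    = {cslc:.12e}")
# angle-factor identity check: cos(atan(sqrt(2R/d))) == sqrt(d/(d+2R))
print("angle equal:", math.isclose(math.cos(math.atan(math.sqrt(2*R/d))),
                                   math.sqrt(d/(d+2*R)), rel_tol=1e-14))
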