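# Idealized extended 10-20 system 36-channel montage on the unit sphere.
# Head-centered coordinates: x toward the right ear, y toward the nasion, z toward the vertex.
# Ten-percent ring electrodes constructed by the standard fractional-arc rules;
# FT9/FT10/TP9/TP10 sit on the equatorial (low-temporal) ring; the remaining
# intermediate electrodes (FC/CP/FT7-8/TP7-8/POz rows) are spherical midpoints of their 10-20 neighbors.
# label x y z
Fp1 -0.293892626146 +0.904508497187 +0.309016994375
Fpz -0.000000000000 +0.951056516295 +0.309016994375
Fp2 +0.293892626146 +0.904508497187 +0.309016994375
F7 -0.769420884294 +0.559016994375 +0.309016994375
F3 -0.415626937777 +0.415626937777 +0.809016994375
Fz -0.000000000000 +0.587785252292 +0.809016994375
F4 +0.415626937777 +0.415626937777 +0.809016994375
F8 +0.769420884294 +0.559016994375 +0.309016994375
FT9 -0.951056516295 +0.309016994375 +0.000000000000
FT7 -0.899983369432 +0.292422323010 +0.323294169065
FC3 -0.514901150355 +0.213279039759 +0.830294439679
FCz +0.000000000000 +0.309016994375 +0.951056516295
FC4 +0.514901150355 +0.213279039759 +0.830294439679
FT8 +0.899983369432 +0.292422323010 +0.323294169065
FT10 +0.951056516295 +0.309016994375 +0.000000000000
T7 -0.951056516295 +0.000000000000 +0.309016994375
C3 -0.587785252292 +0.000000000000 +0.809016994375
Cz +0.000000000000 +0.000000000000 +1.000000000000
C4 +0.587785252292 +0.000000000000 +0.809016994375
T8 +0.951056516295 +0.000000000000 +0.309016994375
TP9 -0.951056516295 -0.309016994375 +0.000000000000
TP7 -0.899983369432 -0.292422323010 +0.323294169065
CP3 -0.514901150355 -0.213279039759 +0.830294439679
CPz -0.000000000000 -0.309016994375 +0.951056516295
CP4 +0.514901150355 -0.213279039759 +0.830294439679
TP8 +0.899983369432 -0.292422323010 +0.323294169065
TP10 +0.951056516295 -0.309016994375 +0.000000000000
P7 -0.769420884294 -0.559016994375 +0.309016994375
P3 -0.415626937777 -0.415626937777 +0.809016994375
Pz -0.000000000000 -0.587785252292 +0.809016994375
P4 +0.415626937777 -0.415626937777 +0.809016994375
P8 +0.769420884294 -0.559016994375 +0.309016994375
POz -0.000000000000 -0.809016994375 +0.587785252292
O1 -0.293892626146 -0.904508497187 +0.309016994375
Oz -0.000000000000 -0.951056516295 +0.309016994375
O2 +0.293892626146 -0.904508497187 +0.309016994375
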