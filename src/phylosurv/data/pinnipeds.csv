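species,stage,rate,rate_se,rate_ci_low,rate_ci_high,se_source
Halichoerus grypus,sexual,0.98,0.003,,,reported_se
Halichoerus grypus,social,0.98,0.003,,,reported_se
Phoca vitulina,yearling,0.78,0.03,0.71,0.84,reported_se
Phoca vitulina,sexual,0.88,0.03,0.78,0.94,reported_se
Phoca vitulina,social,0.88,0.03,0.78,0.94,reported_se
Leptonychotes weddellii,yearling,0.60,0.03,0.51,0.75,reported_se
Leptonychotes weddellii,sexual,0.94,0.02,0.92,0.96,reported_se
Leptonychotes weddellii,social,0.93,0.02,0.91,0.94,reported_se
Mirounga leonina,yearling,0.75,0.051,,,reported_se
Mirounga leonina,sexual,0.74,0.062,,,reported_se
Mirounga leonina,social,0.65,0.128,,,reported_se
Mirounga angustirostris,yearling,0.68,,0.62,0.74,derived_from_ci
Mirounga angustirostris,sexual,0.68,,0.62,0.75,derived_from_ci
Mirounga angustirostris,social,0.69,,0.53,0.82,derived_from_ci
Monachus monachus,social,0.87,,0.81,0.94,derived_from_ci
Monachus schauinslandi,yearling,0.56,0.06,0.43,0.68,reported_se
Monachus schauinslandi,sexual,0.72,0.09,0.65,0.80,reported_se
Monachus schauinslandi,social,0.89,0.03,0.83,0.93,reported_se
Eumetopias jubatus,yearling,0.69,0.02,0.65,0.72,reported_se
Eumetopias jubatus,sexual,0.80,0.02,0.76,0.83,reported_se
Eumetopias jubatus,social,0.73,0.03,0.68,0.78,reported_se
Neophoca cinerea,yearling,0.88,0.02,0.83,0.92,reported_se
Neophoca cinerea,sexual,0.89,0.03,0.82,0.94,reported_se
Neophoca cinerea,social,0.89,0.03,0.82,0.94,reported_se
Phocarctos hookeri,sexual,0.98,,0.90,0.99,derived_from_ci
Phocarctos hookeri,social,0.98,,0.90,0.99,derived_from_ci
Zalophus californianus,yearling,0.76,,0.71,0.80,derived_from_ci
Zalophus californianus,sexual,0.93,,0.91,0.94,derived_from_ci
Zalophus californianus,social,0.89,,0.87,0.89,derived_from_ci
Arctocephalus forsteri,social,0.76,,0.66,0.82,derived_from_ci
Arctocephalus tropicalis,sexual,0.96,0.02,,,reported_se
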