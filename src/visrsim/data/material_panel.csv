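label,ET_kPa,EL_kPa,muT_kPa,muL_kPa,nuTT,nuLT,muL_over_EL
M01,11.74,35.441509433962253,3.2000000000000002,4.7999999999999998,0.83437499999999998,0.5,0.13543441226575814
M02,12.323610141893464,82.780000000000001,3.2000000000000006,4.7999999999999998,0.92556408467085372,0.5,0.05798502053636144
M03,13.61344537815126,62.307692307692299,3.6000000000000001,16.199999999999999,0.89075630252100835,0.5,0.26000000000000006
M04,13.584905660377359,60,3.6000000000000001,16.199999999999999,0.8867924528301887,0.5,0.27000000000000002
M05,15.203619909502262,40,4.2000000000000002,10.4,0.80995475113122173,0.5,0.26000000000000001
M06,18.823529411764707,80,5,20.800000000000001,0.88235294117647056,0.5,0.26000000000000001
M07,14.814814814814815,50,4,10.5,0.85185185185185186,0.5,0.20999999999999999
M08,16.849816849816847,50,4.5999999999999979,16,0.83150183150183155,0.5,0.32000000000000001
M09,19.494584837545126,50,5.4000000000000012,21,0.80505415162454874,0.5,0.41999999999999998
M10,21.818181818181817,60,5.9999999999999991,27,0.81818181818181823,0.5,0.45000000000000001
M11,24.960000000000001,75.771428571428629,6.7999999999999989,40.799999999999997,0.83529411764705896,0.5,0.5384615384615381
M12,12.534562211981568,40,3.3999999999999999,6.7999999999999998,0.84331797235023043,0.5,0.17000000000000001
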