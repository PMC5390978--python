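model,variance,aic,akaike_weight,param,estimate,ci_low,ci_high
simple,none,-162,6.2e-24,A_prime,2.5,-1.5,6.5
simple,none,-162,6.2e-24,B,26.1,-0.2,52.3
simple,exponential,-255,7.2e-4,A_prime,2.5,-1.0,5.8
simple,exponential,-255,7.2e-4,B,26.1,13.6,38.6
simple,power,-237,8.01e-8,A_prime,2.5,-2.0,7.0
simple,power,-237,8.01e-8,B,26.1,-3.0,55.1
heterogeneous,none,-158,8.8e-25,A1_prime,3.2,-9.0,15.4
heterogeneous,none,-158,8.8e-25,B1,21.6,-30.0,73.0
heterogeneous,none,-158,8.8e-25,A2_prime,0.04,-0.43,-0.51
heterogeneous,none,-158,8.8e-25,B2,1047,-41689,43784
heterogeneous,exponential,-254,5.4e-4,A1_prime,3.2,-2.2,8.6
heterogeneous,exponential,-254,5.4e-4,B1,21.6,8.7,34.4
heterogeneous,exponential,-254,5.4e-4,A2_prime,0.04,0.03,0.10
heterogeneous,exponential,-254,5.4e-4,B2,1047,-5121,7215
heterogeneous,power,-269,0.791,A1_prime,3.2,-2.4,8.7
heterogeneous,power,-269,0.791,B1,21.6,4.02,39.2
heterogeneous,power,-269,0.791,A2_prime,0.04,0.02,0.10
heterogeneous,power,-269,0.791,B2,1022,-2130,4174
mixed_equal,none,-160,2.4e-24,A_prime,2.7,-2.6,8.0
mixed_equal,none,-160,2.4e-24,B,24.4,-4.7,53.6
mixed_equal,none,-160,2.4e-24,C_prime,0.001,-0.009,0.012
mixed_equal,exponential,-253,3.5e-4,A_prime,2.7,-1.2,6.6
mixed_equal,exponential,-253,3.5e-4,B,24.4,12.4,36.4
mixed_equal,exponential,-253,3.5e-4,C_prime,0.0005,-0.001,0.002
mixed_equal,power,-266,0.207,A_prime,1.8,-2.7,3.9
mixed_equal,power,-266,0.207,B,31.3,11.7,50.9
mixed_equal,power,-266,0.207,C_prime,0.001,0.00005,0.002
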