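# WAG amino-acid replacement model
# lower-triangle exchangeabilities (row 2..20), then equilibrium frequencies
# amino-acid order: A R N D C Q E G H I L K M F P S T W Y V
0.551571
0.509848 0.738998
1.027040 0.908598 1.582850
1.416720 0.316954 0.193335 0.397915
0.906265 0.893496 0.210494 1.438550 3.370790
2.121110 0.113133 0.240735 2.006010 0.635346 0.147304
0.528191 3.035500 0.439157 0.584665 2.137150 0.186979 0.497671
5.351420 0.683162 0.102711 0.679489 1.224190 0.554413 1.163920 0.381533
0.251849 5.429420 0.265256 1.543640 0.947198 1.125560 3.956290 0.554236 0.131528
3.0120100 0.1982210 0.0961621 0.1950810 3.9742300 2.0300600 0.0719167 1.0860000 0.1962460 0.0302949
0.6167830 6.1741600 0.8655840 0.9306760 0.0394370 0.0848047 0.4798550 0.1037540 0.0467304 0.4239840 1.0717600
0.3748660 0.1297670 0.3257110 0.1523350 0.0988179 0.0213520 0.3066740 0.2489720 0.1701350 0.3842870 0.0740339 0.3904820
0.398020 0.109404 1.407660 0.512984 0.717070 0.543833 1.002140 5.469470 0.330052 4.294110 0.113917 0.869489 3.894900
1.5452600 0.0999208 0.9333720 1.0288700 0.8579280 0.2157370 0.2277100 0.3012810 0.5677170 0.5700250 0.1273950 0.1542630 2.5844300 0.3151240
0.0811339 0.6823550 0.7049390 0.8227650 0.1565570 0.1963030 0.5887310 0.2494100 0.0304501 0.0613037 0.3735580 0.1741000 0.0499310 0.2435700 1.3418200
0.225833 0.336983 0.103604 0.187247 0.138190 0.499462 0.890432 0.404141 0.679371 0.696198 0.740169 0.473307 0.262569 3.873440 0.118358 3.170970
0.3238320 4.2574600 1.0594700 0.0999288 0.3194400 1.4581600 0.2124830 0.4201700 7.8213000 0.2575550 4.8540200 2.1151700 0.4158440 0.3447390 0.3266220 0.6653090 0.3986180
1.800340 0.934276 0.088836 0.556896 0.967130 1.386980 0.137505 0.133264 0.305434 1.190630 0.171329 0.493905 1.516120 0.515706 0.428437 2.058450 0.161444 0.545931
0.171903 1.529640 6.454280 0.649892 1.613280 0.795384 0.139405 0.216046 0.314887 4.378020 0.523742 0.786993 0.232739 0.110864 0.291148 1.388230 2.485390 0.365369 0.314730
0.08662790866 0.04397200440 0.03908940391 0.05704510570 0.01930780193 0.03672810367 0.05805890581 0.08325180833 0.02443130244 0.04846600485 0.08620900862 0.06202860620 0.01950270195 0.03843190384 0.04576310458 0.06951790695 0.06101270610 0.01438590144 0.03527420353 0.07089560709
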