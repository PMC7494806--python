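accession_id,species,chromosome_number,ploidy,doi,origin,biological_status,group
CIP 460360,I. australis,30,2x,10.18730/82SY,PRY,W,B
CIP 460296,I. australis,30,2x,10.18730/80T4,ARG,W,B
CIP 460345,I. australis,30,2x,10.18730/82AF,PRY,W,D
CIP 460585,I. australis,30,2x,10.18730/89GQ,ARG,W,D
CIP 460164,I. australis,30,2x,10.18730/7Y5Y,PRY,W,D
CIP 430434,I. batatas,60,4x,10.18730/852X,JAP,W,B
CIP 460577,I. batatas,60,4x,10.18730/898F,ECU,TC,B
CIP 440132,I. batatas Beauregard,90,6x,10.18730/65R1,USA,AC,B
CIP 440166,I. batatas Tanzania,90,6x,10.18730/66NY,UGA,TC,B
CIP 105269.232,I. batatas BxT,90,6x,10.18730/SK7J$,PER,Br,B
CIP 113641.086,I. batatas BxT,90,6x,10.18730/SK7K=,PER,Br,D
CIP 460077,I. cordatotriloba,30,2x,10.18730/7W75,MEX,W,B
CIP 460149,I. cynanchifolia,30,2x,10.18730/7XTK,BRA,W,B
CIP 460556,I. cynanchifolia,30,2x,10.18730/88M*,BRA,W,D
CIP 460555,I. cynanchifolia,30,2x,10.18730/88KZ,BRA,W,D
CIP 460610,I. grandifolia,30,2x,10.18730/89QY,BRA,W,B
CIP 460201,I. grandifolia,30,2x,10.18730/7YZK,ARG,W,D
CIP 460583,I. grandifolia,30,2x,10.18730/89EN,URU,W,D
CIP 460452,I. grandifolia,30,2x,10.18730/85MA,ARG,W,D
CIP 460337,I. grandifolia,30,2x,10.18730/8238,PRY,W,D
CIP 460619,I. leucantha,30,2x,10.18730/89T~,COL,W,B
CIP 460204,I. leucantha,30,2x,10.18730/7Z2P,ARG,W,D
CIP 460028,I. ramosissima,30,2x,10.18730/7V58,ECU,W,B
CIP 460032,I. ramosissima,30,2x,10.18730/7V9C,BOL,W,B
CIP 460566,I. ramosissima,30,2x,10.18730/88Y5,PER,W,B
CIP 460567,I. ramosissima,30,2x,10.18730/88Z6,PER,W,B
CIP 460005,I. ramosissima,30,2x,10.18730/7THS,PER,W,B
CIP 460047,I. ramosissima,30,2x,10.18730/7VNR,PER,W,B
CIP 460722,I. ramosissima,30,2x,10.18730/8B0$,ARG,W,B
CIP 460036,I. ramosissima,30,2x,10.18730/7VCF,BOL,W,D
CIP 460131,I. splendor-sylvae,30,2x,10.18730/7XE7,MEX,W,B
CIP 460373,I. splendor-sylvae,30,2x,10.18730/8355,NIC,W,B
CIP 460383,I. splendor-sylvae,30,2x,10.18730/83FF,NIC,W,B
CIP 460528,I. tiliacea,60,4x,10.18730/87V7,CUB,W,B
CIP 460531,I. tiliacea,60,4x,10.18730/87YA,CUB,W,B
CIP 460663,I. trifida,30,2x,10.18730/8A9B,MEX,W,C
CIP 113735.283,I. trifida,30,2x,10.18730/SK7P1,PER,Br,C
CIP 107665.9,I. trifida,30,2x,10.18730/SK7MU,PER,W,C
CIP 460026,I. trifida,30,2x,10.18730/7V36,COL,W,D
CIP 460430,I. trifida,30,2x,10.18730/84YS,CUB,W,D
CIP 460377,I. trifida,30,2x,10.18730/8399,NIC,W,D
CIP 460745,I. trifida,30,2x,10.18730/8BDA,GUA,W,D
CIP 460429,I. trifida,30,2x,10.18730/84XR,NIC,W,D
CIP 460096,I. trifida,30,2x,10.18730/7WKH,VEN,W,D
CIP 460195,I. trifida,30,2x,10.18730/7YSD,VEN,W,D
CIP 460022,I. trifida,30,2x,10.18730/7V03,COL,W,D
CIP 113735.258,I. trifida,30,2x,10.18730/SK7N0,PER,Br,D
CIP 113735.302,I. trifida,30,2x,10.18730/SK7Q2,PER,Br,D
CIP 113735.329,I. trifida,30,2x,10.18730/SK7R3,PER,Br,D
CIP 107665.19,I. trifida,30,2x,10.18730/SK7H~,PER,W,D
CIP 460021,I. trifida,30,2x,10.18730/7TZ2,VEN,W,D
CIP 460309,I. triloba,30,2x,10.18730/817H,PRY,W,B
CIP 460116,I. triloba,30,2x,10.18730/7X5=,COL,W,C
CIP 460560,I. triloba,30,2x,10.18730/88RU,PER,W,D
CIP 460052,I. triloba,30,2x,10.18730/7VSW,VEN,W,D
CIP 460093,I. triloba,30,2x,10.18730/7WJG,DOM,W,D
CIP 460517,I. triloba,30,2x,10.18730/87H$,ECU,W,D
CIP 460784,I. triloba,30,2x,10.18730/8C1Y,JAM,W,D
CIP 460078,I. triloba,30,2x,10.18730/7W86,MEX,W,D
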